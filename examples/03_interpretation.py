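"""Interpret a fitted model through its weight matrix.

Each column of the fitted W belongs to one response anchor; large
positive entries mean "being structurally close to this structure
anchor predicts a small response distance to that response anchor".
Flipping the sign of columns tied to low-response anchors (response
below 5) and summing rows ranks the structure anchors most strongly
associated with high (positive score) or low (negative score) activity.
"""

import adaptor as ad

train = ad.make_synthetic_qsar(300, seed=4).data
model = ad.fit_adaptor(train, ad.AnchorConfig(seed=4))

resp = dict(zip(train.ids, train.responses))
anchors = model.model.response_anchor_ids
values = model.model.response_anchor_values
print("response anchors (k-means):",
      ", ".join(f"{a}({v:.2f})" for a, v in zip(anchors, values)))

pos, neg = ad.top_anchors_for_response_anchor(model.model, 0, k=3)
print(f"\ntop weights for response anchor {anchors[0]} (t={values[0]:.2f}):")
for a in pos:
    print(f"  +{a.weight:.3f}  {a.anchor_id}  (response {resp[a.anchor_id]:.2f})")
for a in neg:
    print(f"  {a.weight:.3f}  {a.anchor_id}  (response {resp[a.anchor_id]:.2f})")

summary = ad.adjusted_weight_sums(model.model, low_response_threshold=5.0)
print("\ncritical structure anchors by adjusted-weight sum:")
print(summary.head(5).to_string(index=False))
# Anchors with large positive scores are compounds whose structural
# neighborhood is associated with high responses; large negative scores
# mark neighborhoods associated with low responses.
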