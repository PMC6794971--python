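"""Audit the five-channel CNN without training it.

The adaptive kernel rule gives each branch a kernel of ceil(x/2) for x
input features: (2,1) for the 4-feature ECG branch and (8,1) for the
15-feature accelerometer branch.  Parameter counts and output widths
follow from valid-convolution arithmetic alone.
"""

from wearstate import audit_table, build_model, count_parameters, kernel_shape

spec = build_model()
for ch, x in spec.channel_features.items():
    print(f"{ch:5s}: {x:2d} features -> kernel {kernel_shape(x)}")

table = audit_table(spec)
print("\n", table.to_string(index=False))
total = count_parameters(spec)["total"]
print(f"\ntotal trainable parameters: {total}")
print("The concatenation of five 32-unit branch outputs is 160 wide; the "
      "trunk reduces it to 32 units and a 5-way softmax.")
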