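"""Generate one synthetic subject and convert the raw streams to SI units.

The chest unit emits 16-bit ADC words; midscale (32768) is electrical
zero.  Conversion maps ECG onto a +/-1.5 mV swing, EMG onto +/-1.5 uV and
respiration onto +/-50 % displacement.
"""

import numpy as np

from wearstate import ConversionSpec, convert_signal, generate_subject
from wearstate.synthetic import CohortParams

params = CohortParams(n_subjects=1, total_duration_s=300.0, seed=1)
rec = generate_subject("demo", params, seed=1)

print(f"subject {rec.subject_id}: {rec.duration_s:.0f} s, "
      f"{len(rec.streams)} streams, {len(rec.labels)} labels @ 700 Hz")
for name, st in sorted(rec.streams.items()):
    v = np.asarray(st.values, dtype=float)
    print(f"  {name:10s} {st.rate_hz:6.0f} Hz  n={len(st):7d}  "
          f"range [{v.min():9.1f}, {v.max():9.1f}]")

ecg_mv = convert_signal("ecg", rec.streams["ecg"].values, ConversionSpec())
print(f"\nECG raw {rec.streams['ecg'].values[:3]} -> {np.round(ecg_mv[:3], 4)} mV")
print("A raw value of 32768 (midscale) maps to exactly 0 mV; the synthetic "
      "beat pulses push the signal toward the upper rail.")
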