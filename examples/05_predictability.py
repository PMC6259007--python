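"""Node predictability: shared variance of each symptom with the rest.

Mean R^2 near 0.5 means half of each symptom's variance is carried by its
neighbors; the amnesia item (D1) is far below the rest.
"""
import symnet as sn

data = sn.sample_ordinal(sn.preset_ptsd17("clinical", n=3000, seed=5))
r2 = sn.predictability(data)
print(r2.round(3).to_string())
print(f"\nmean predictability = {sn.mean_predictability(data):.3f}")
print(f"least predictable: {r2.idxmin()} ({r2.min():.2f});"
      f" most predictable: {r2.idxmax()} ({r2.max():.2f})")
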