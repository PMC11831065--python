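"""Generate a small synthetic cohort and check coherence against the closed form.

The generator plants a shared 12 Hz source on two channels; because the model
is linear (shared band-limited source + independent 1/f noise), the population
magnitude-squared coherence at the source frequency is known exactly.
"""

import numpy as np

from neurocoh import SourceSpec, SynthConfig, WelchConfig, default_montage, msc, welch_spectra
from neurocoh.preprocessing import EpochSet
from neurocoh.synthetic import expected_coherence, generate_cohort

montage = default_montage().subset(["F3", "F4"])
cfg = SynthConfig(
    montage=montage,
    n_per_group=2,
    sources=(SourceSpec(center_freq=12.0, bandwidth=2.0, target_channels=("F3", "F4"),
                        gain=1.0, jitter_sigma=0.0),),
    epoch_s=60.0,
    n_epochs=5,
    seed=42,
)

cohort = generate_cohort(cfg)
print(f"cohort: {len(cohort)} subjects, {cohort[0].data.shape[0]} channels, "
      f"{cohort[0].duration_s:.0f} s each")

rec = cohort[0]
es = EpochSet(subject_id=rec.subject_id, group=rec.group, condition="EO",
              epochs=[rec.data], fs=rec.fs, montage=montage)
se = welch_spectra(es, WelchConfig())
c = msc(se, ("F3", "F4"))
bin12 = int(np.argmin(np.abs(se.freqs - 12.0)))
analytic = expected_coherence(cfg, "F3", "F4", 12.0)

print(f"empirical MSC(F3,F4) at 12 Hz : {c[bin12]:.3f}")
print(f"analytic  MSC(F3,F4) at 12 Hz : {analytic:.3f}")
print(f"MSC at 30 Hz (no source there): {c[int(np.argmin(np.abs(se.freqs-30)))]:.3f}")
print("-> the estimator sits on the closed-form value at the source frequency "
      "and near the 1/K bias floor away from it.")
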