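"""Band-averaged coherence profiles for one subject, eyes open vs eyes closed.

The demo cohort has a posterior alpha source that is stronger with eyes
closed (the Berger effect) and a frontal 11.2-12.8 Hz coupling present with
eyes open only — both visible in the band matrices.
"""

from neurocoh import WelchConfig, demo_config, preprocess_recording, subject_coherence_profile
from neurocoh.synthetic import generate_subject

cfg = demo_config(n_per_group=2, seed=3)
rec = generate_subject(cfg, 0, "control")
eo, ec = preprocess_recording(rec)
p_eo = subject_coherence_profile(eo, WelchConfig())
p_ec = subject_coherence_profile(ec, WelchConfig())

print(f"subject {p_eo.subject_id}: K = {p_eo.K} Welch segments per condition\n")
print("pair            band     EO      EC")
for pair, band in [(("O1", "O2"), "alpha"), (("O1", "O2"), "alpha1"),
                   (("F4", "F8"), "alpha3"), (("F4", "F8"), "delta"),
                   (("Fz", "Cz"), "theta")]:
    print(f"{pair[0]:>3}-{pair[1]:<10} {band:<8} {p_eo.value(band, *pair):.3f}   "
          f"{p_ec.value(band, *pair):.3f}")
print("\n-> posterior alpha coherence rises with eyes closed; the frontal "
      "11-13 Hz coupling (F4-F8 alpha3) is present with eyes open only; "
      "delta shows only the ~1/K estimator bias.")
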