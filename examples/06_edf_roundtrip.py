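"""Write a subject to EDF+ (annotations included) and read it back via mne."""

import tempfile
from pathlib import Path

import numpy as np

from neurocoh import demo_config
from neurocoh.io import read_edf, write_edf
from neurocoh.synthetic import generate_subject

cfg = demo_config(n_per_group=2, seed=1)
rec = generate_subject(cfg, 0, "case")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / f"{rec.subject_id}.edf"
    write_edf(rec, path)
    print(f"wrote {path.name}: {path.stat().st_size / 1e6:.1f} MB")
    back = read_edf(path)

err = np.max(np.abs(back.data[:, : rec.n_samples] - rec.data))
quant = np.abs(rec.data).max() / 32767
print(f"subject/group restored : {back.subject_id} / {back.group}")
print(f"annotations restored   : {back.annotations == rec.annotations} "
      f"({len(back.annotations)} EO/EC blocks)")
print(f"max reconstruction err : {err:.2e} (16-bit quantization step {quant:.2e})")
print("-> EDF+ round trip is lossless up to 16-bit quantization.")
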