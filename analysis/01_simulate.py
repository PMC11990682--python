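"""Generate the two default synthetic flour studies.

Writes per-sample feature tables, MS/MS spectra (MGF), class labels and
the ground truth for the grape-seed (GSFC vs GSFL) and olive-stone
(OSFC vs OSFL) studies under results/studies/.
"""
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from flourms.io_formats import write_feature_table, write_mgf
from flourms.synthetic import generate_study, gsf_profile, osf_profile

SEED = 1
OUT = os.path.join(os.path.dirname(__file__), "..", "scratch", "studies")

for name, profile in (("gsf", gsf_profile), ("osf", osf_profile)):
    cfg = profile(SEED)
    study = generate_study(cfg)
    out = os.path.join(OUT, name)
    os.makedirs(out, exist_ok=True)
    for t in study.tables:
        write_feature_table(t, os.path.join(out, f"{t.sample_id}.csv"))
    write_mgf(study.spectra, os.path.join(out, "spectra.mgf"))
    with open(os.path.join(out, "ground_truth.json"), "w") as fh:
        fh.write(study.truth.to_json())
    with open(os.path.join(out, "labels.csv"), "w") as fh:
        fh.write("sample_id,class_label\n")
        for sid, lab in study.truth.labels.items():
            fh.write(f"{sid},{lab}\n")
    n_compounds = len(cfg.compound_specs)
    print(f"{name.upper()}: {len(study.tables)} samples, "
          f"{n_compounds} planted compounds + IS + {cfg.n_noise_features} noise "
          f"features = {study.truth.n_total_features} ground-truth features "
          f"({len(study.spectra)} MS/MS spectra)")
print(f"written to {os.path.normpath(OUT)} (seed {SEED})")
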