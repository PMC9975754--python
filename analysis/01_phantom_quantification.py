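"""Render the demo phantom and quantify it under both reader modes.

Shows that liver-referenced detection (mean + 2 SD in a 3-cm sphere)
followed by per-lesion 41%-of-SUVmax isocontouring recovers the three
malignant lesions, rejects the physiologic decoys, and lands MTV close
to the analytic ellipsoid volumes.  Writes per-lesion and per-reader
tables to results/phantom/.
"""

import json
from pathlib import Path

import pandas as pd

from petburden.lesions import lesion_table, percent_difference
from petburden.phantom import default_phantom_spec, generate_phantom
from petburden.pipeline import FLOAT_FMT, quantify_phantom_both_readers

OUT = Path(__file__).resolve().parent.parent / "results" / "phantom"
OUT.mkdir(parents=True, exist_ok=True)

spec = default_phantom_spec(seed=0)
vol, truth = generate_phantom(spec)
quant = quantify_phantom_both_readers(vol, truth, spec.liver.center_mm)
ref = quant["liver"]
print(f"liver reference: mean {ref.mean_suv:.3f}, SD {ref.sd_suv:.3f}, "
      f"threshold {ref.detection_threshold:.3f}, sphere {ref.sphere_volume_ml:.2f} ml")

true_mtv = sum(v for k, v in truth.analytic_volume_ml.items()
               if truth.labels[k] == "malignant")
rows = []
for reader in ("M", "A"):
    s = quant[reader]["summary"]
    lesion_table(quant[reader]["lesions"]).to_csv(
        OUT / f"lesions_{reader}.csv", index=False, float_format=FLOAT_FMT)
    rows.append({"reader": reader, "mtv_ml": s.mtv_ml, "tlg_suvml": s.tlg_suvml,
                 "lesion_count": s.lesion_count,
                 "mtv_pct_error_vs_truth": percent_difference(true_mtv, s.mtv_ml)})
    print(f"reader {reader}: MTV {s.mtv_ml:.2f} ml (truth {true_mtv:.2f}), "
          f"TLG {s.tlg_suvml:.2f} SUV*ml, {s.lesion_count} lesions")

pd.DataFrame(rows).to_csv(OUT / "summary.csv", index=False, float_format=FLOAT_FMT)
(OUT / "ground_truth.json").write_text(json.dumps(
    [{"structure": k, "label": truth.labels[k],
      "analytic_volume_ml": truth.analytic_volume_ml[k],
      "peak_suv": truth.peak_suv[k]} for k in truth.masks], indent=2))
print(f"tables -> {OUT}")
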