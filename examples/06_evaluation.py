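"""Evaluate a site-wise interface predictor and aggregate over proteins."""

import numpy as np

from featkit.evaluate import aggregate, confusion, evaluate_sites, metrics

rng = np.random.default_rng(0)

# two synthetic proteins: labels plus a noisy score correlated with them
reports = []
for n, noise in ((60, 0.2), (120, 0.35)):
    y = rng.integers(0, 2, size=n)
    score = np.clip(0.7 * y + rng.normal(0.3, noise, size=n), 0, 1)
    rep = evaluate_sites(y, score, threshold=0.5)
    reports.append(rep)
    print(f"protein with {n} sites: precision="
          f"{rep.precision:.3f} recall={rep.recall:.3f} "
          f"mcc={rep.mcc:.3f} auroc={rep.auroc:.3f}")

pooled = aggregate(reports, mode="pooled")
print(f"pooled over all sites: accuracy={pooled.accuracy:.3f} "
      f"mcc={pooled.mcc:.3f}")
macro = aggregate(reports, mode="macro")
print(f"macro (per-protein mean): mcc={macro['mcc']:.3f}")
# pooled weights every site equally; macro weights every protein equally —
# they diverge when class balance differs across proteins

rep = metrics(confusion([1, 0, 1, 0], [0.9, 0.2, 0.4, 0.6]))
print(f"toy confusion (tp,fp,fn,tn)=({rep.tp},{rep.fp},{rep.fn},{rep.tn}), "
      f"precision={rep.precision:.2f}")
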