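#!/usr/bin/env python
"""Correlate genus abundances with age and with DMR methylation.

Genus-age trends use Pearson p < 0.1 (relaxed, trend-level screening at
n = 10 subjects).  A DMR-genus pair is linked when >= 2 member CpGs
correlate with the genus abundance at p < 0.1.  Writes
results/genus_trends.tsv and results/dmr_genus_links.tsv.
"""

from pathlib import Path

import pandas as pd

from agedmr.dmr import call_dmrs
from agedmr.microbiome import genus_age_trends, link_dmrs_to_genera
from agedmr.screen import screen_age_cpgs
from agedmr.simulate import simulate_cohort

ROOT = Path(__file__).resolve().parents[1]

cohort = simulate_cohort(seed=42)
res = screen_age_cpgs(cohort.beta, cohort.samples)
dmrs = call_dmrs(res.decreasing, cohort.manifest) + \
    call_dmrs(res.increasing, cohort.manifest)

trends = genus_age_trends(cohort.abundance, cohort.samples)
selected = [t for t in trends if t.selected]
print(f"{len(selected)}/{len(trends)} genera show an age trend at p < 0.1:")
for t in sorted(selected, key=lambda t: t.p_value):
    truth_c = cohort.truth.genera.loc[t.genus, "coupling"]
    tag = " (coupled to a planted region)" if truth_c > 0 else ""
    print(f"  {t.genus}: r = {t.r:+.2f}, p = {t.p_value:.3f}, "
          f"{t.direction}{tag}")

links = link_dmrs_to_genera(cohort.beta, cohort.abundance, cohort.samples,
                            dmrs, trends)
linked = [l for l in links if l.linked]
print(f"{len(linked)} linked DMR-genus pairs "
      f"({len(links)} pairs tested over {len(dmrs)} DMRs)")

(ROOT / "results").mkdir(exist_ok=True)
pd.DataFrame(
    [(t.genus, t.r, t.p_value, t.n_used, t.direction, int(t.selected))
     for t in trends],
    columns=["genus", "r", "p", "n_used", "direction", "selected"],
).set_index("genus").to_csv(ROOT / "results" / "genus_trends.tsv", sep="\t")
pd.DataFrame(
    [(l.dmr_id, l.genus, l.n_cpgs_passing, l.avg_meth_r, l.avg_meth_p,
      int(l.linked)) for l in links],
    columns=["dmr_id", "genus", "n_cpgs_passing", "avg_meth_r", "avg_meth_p",
             "linked"],
).to_csv(ROOT / "results" / "dmr_genus_links.tsv", sep="\t", index=False)
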