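#!/usr/bin/env python
"""Generate the default synthetic study cohort and inspect its structure.

22 controls aged 3.5-17.5 y plus 10 UC and 10 CD subjects; 5,000 CpG
probes of which 180 sit in 40 planted age-drift regions (20 decreasing,
20 increasing, span effect 0.25, noise sd 0.03); 25 genera with 5 coupled
to planted regions; 10 controls carry abundance data.  Full tables go to
scratch/cohort (large); the small truth tables go to results/.
"""

from pathlib import Path

from agedmr.simulate import simulate_cohort, write_cohort

ROOT = Path(__file__).resolve().parents[1]

cohort = simulate_cohort(seed=42)
paths = write_cohort(cohort, ROOT / "scratch" / "cohort")

results = ROOT / "results"
results.mkdir(exist_ok=True)
cohort.truth.regions.to_csv(results / "truth_regions.tsv", sep="\t")
cohort.truth.genera.to_csv(results / "truth_genera.tsv", sep="\t")

t = cohort.truth
print(f"cohort: {len(cohort.samples.df)} subjects "
      f"({(cohort.samples.df['group'] == 'control').sum()} controls), "
      f"{len(cohort.manifest)} probes")
print(f"planted: {t.probes['planted'].sum()} CpGs in {len(t.regions)} regions "
      f"({(t.regions['direction'] == 'decreasing').sum()} decreasing)")
print(f"disease-linked regions: "
      f"{(t.regions['disease'] == 'UC').sum()} UC, "
      f"{(t.regions['disease'] == 'CD').sum()} CD")
print(f"abundance: {cohort.abundance.df.shape[0]} genera x "
      f"{cohort.abundance.df.shape[1]} subjects; "
      f"{(t.genera['coupling'] > 0).sum()} genera coupled to regions")
print(f"full tables written under {paths['beta'].rsplit('/', 1)[0]}/")
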