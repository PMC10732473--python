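"""SNP presence filtering and top-k overlap between two association maps.

Plants 20 strongly group-diverged SNPs and 20 score-affecting SNPs with 6
in common (Balding-Nichols background divergence elsewhere), then checks
how many SNPs the two top-20 lists share.
"""

import numpy as np

from connaudit import (
    SyntheticSpec,
    correlate_features,
    filter_snps,
    generate_cohort,
    overlap_count,
    plant_snp_overlap,
    top_k,
)

spec = plant_snp_overlap(
    SyntheticSpec(n=800, scenario="confound", fst=0.05, seed=3), k=20, shared=6
)
cohort = generate_cohort(spec)

kept = filter_snps(cohort.snps, min_subjects=700)
print(f"SNPs observed in >= 700 of {cohort.n_subjects} subjects: "
      f"{kept.n_snps} of {cohort.snps.n_snps}")

dosages = kept.filled()  # zero-fill only after the presence filter
ids = np.array(kept.snp_ids)
race_map = correlate_features(dosages, cohort.phenotypes.data["race_code"], feature_ids=ids)
wrat_map = correlate_features(dosages, cohort.phenotypes.data["wrat"], feature_ids=ids)

race_top = [str(s) for s in top_k(race_map, 20)]
wrat_top = [str(s) for s in top_k(wrat_map, 20)]
shared = overlap_count(race_top, wrat_top)
print(f"top-20 group-associated SNPs:  {race_top[:5]} ...")
print(f"top-20 score-associated SNPs:  {wrat_top[:5]} ...")
print(f"SNPs in both top-20 lists: {shared} (planted: 6)")
print()
print("An overlap far above the hypergeometric baseline (~0.4 of 20 here)")
print("suggests the score-associated SNPs largely tag ancestry, not achievement.")
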