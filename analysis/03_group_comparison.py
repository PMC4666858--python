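#!/usr/bin/env python
"""Group statistics on the measured R values.

Flags Tukey-fence outliers per treatment arm, pools washed/unwashed arms of
the same protein when a pooled-variance test finds no difference, compares
the proteins with the pooled-variance two-sample t-test (SEM of the
difference, 95 % CI, significance by CI-excludes-0), and writes the
comparison table to results/group_comparison.csv.

Run from the repository root after 02:
    python analysis/03_group_comparison.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fiberratio.group_stats import (
    PoolingRefusal,
    RGroup,
    flag_outliers,
    pool_washed_unwashed,
    pooled_two_sample_test,
    sem_of_mean,
)

RESULTS = Path("results")


def main() -> None:
    df = pd.read_csv(RESULTS / "fibers.csv")
    arms: dict[tuple[str, bool], RGroup] = {}
    for (enzyme, washed), sub in df.groupby(["enzyme", "washed"]):
        values = sub["R"].to_numpy(dtype=float)
        flags = flag_outliers(values) if len(values) >= 4 else \
            np.zeros(len(values), dtype=bool)
        arms[(enzyme, washed)] = RGroup(enzyme, values, washed, flags)
        if flags.any():
            print(f"  {enzyme} washed={washed}: "
                  f"{flags.sum()} suspected outlier(s) flagged")

    groups: dict[str, RGroup] = {}
    for enzyme in sorted({e for e, _ in arms}):
        gw = arms[(enzyme, True)].without_outliers()
        gu = arms[(enzyme, False)].without_outliers()
        try:
            groups[enzyme] = pool_washed_unwashed(gw, gu)
            print(f"  {enzyme}: washed/unwashed pooled "
                  f"(n={groups[enzyme].n})")
        except PoolingRefusal as refusal:
            groups[enzyme] = gw if gw.n >= gu.n else gu
            print(f"  {enzyme}: pooling refused ({refusal})")

    rows = []
    labels = sorted(groups)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            test = pooled_two_sample_test(groups[a], groups[b])
            rows.append({"group1": a, "group2": b, **test.as_dict()})
            print(
                f"{a} (mean R {test.mean1:.3f} ± "
                f"{sem_of_mean(groups[a].R_values):.3f} SEM, n={test.n1}) vs "
                f"{b} (mean R {test.mean2:.3f} ± "
                f"{sem_of_mean(groups[b].R_values):.3f} SEM, n={test.n2}): "
                f"diff {test.mean_diff:.3f}, "
                f"95 % CI [{test.ci_low:.3f}, {test.ci_high:.3f}] -> "
                f"{'significant' if test.significant else 'not significant'}"
            )
    out = RESULTS / "group_comparison.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
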