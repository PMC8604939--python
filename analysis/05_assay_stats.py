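"""Plate-count statistics on the simulated editing assay.

Computes per-replicate editing efficiencies, flags (and retains) Tukey-fence
outliers, runs the omnibus ANOVA and Levene's variance test across ssODN
designs, then the two post-hoc families: Dunnett's many-to-one test of each
modified ssODN against the unmodified control, and Games-Howell pairwise
comparisons for the unequal-variance setting. Writes
results/assay_summary.tsv, results/assay_dunnett.tsv and
results/assay_games_howell.tsv.
"""

from pathlib import Path

import pandas as pd

from sstrkit import assaystats

ROOT = Path(__file__).resolve().parent.parent / "results"
CONTROL = "unmodified"


def main() -> None:
    counts = pd.read_csv(ROOT / "simulated" / "plate_counts.tsv", sep="\t")
    counts["efficiency_pct"] = assaystats.editing_efficiency(counts)
    truth = pd.read_csv(ROOT / "simulated" / "truth_assay.tsv", sep="\t")

    summary = assaystats.summarize_groups(counts).merge(truth, on="genotype")
    summary.to_csv(ROOT / "assay_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"outliers flagged (retained in all statistics): "
          f"{int(summary['n_outliers'].sum())}/{int(summary['n'].sum())}")

    groups = assaystats.groups_from_frame(counts)
    anova = assaystats.basic_tests(list(groups.values()), "anova")
    levene = assaystats.basic_tests(list(groups.values()), "levene")
    print(f"\nANOVA across designs: F{anova.df} = {anova.statistic:.3f}, "
          f"p = {anova.p:.3g}")
    print(f"Levene (mean-centred): p = {levene.p:.3g}")

    dunnett = assaystats.compare_to_control(groups, CONTROL)
    dunnett.to_csv(ROOT / "assay_dunnett.tsv", sep="\t", index=False)
    print("\nDunnett vs unmodified control:")
    print(dunnett[["comparison", "estimate", "statistic", "p_adj"]]
          .to_string(index=False))

    gh = assaystats.pairwise_unequal_var(groups, CONTROL)
    gh.to_csv(ROOT / "assay_games_howell.tsv", sep="\t", index=False)
    print("\nGames-Howell vs unmodified control (Tukey corrected):")
    print(gh[["group_a", "group_b", "estimate", "statistic", "df", "p_adj"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
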