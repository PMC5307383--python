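"""Phenotype group comparisons and the miR-phenotype correlation heatmap.

Runs the Shapiro-gated group tests over every phenotype (independent t /
Mann-Whitney for either postmenopausal group vs PRE, paired t / Wilcoxon
within twin pairs), then correlates the differentially
expressed miRs with the phenotype panel (Spearman, BH over the grid) and
draws the complete-linkage clustered heatmap with two-tier significance
marks.
"""

from pathlib import Path

import pandas as pd

from exomir import (
    cluster_heatmap,
    compare_groups_table,
    read_count_matrix,
    read_sample_table,
    spearman_association,
    write_results,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    study = ROOT / "simulated_study"
    counts = read_count_matrix(study / "counts.tsv")
    samples = read_sample_table(study / "samples.csv")

    group_tests = compare_groups_table(samples)
    n_sig = int((group_tests["p"] < 0.05).sum())
    print(f"{n_sig}/{len(group_tests)} phenotype comparisons significant at 0.05")

    de = pd.read_csv(ROOT / "de" / "contrasts.tsv", sep="\t")
    sig = de.loc[de["q"] < 0.05, "mir_id"].unique()
    sel = list(sig) if len(sig) >= 2 else counts.mir_ids[:20]
    print(f"correlating {len(sel)} miRs with {len(samples.phenotype_names)} phenotypes")

    assoc = spearman_association(counts.subset(mir_ids=sel), samples)
    out = ROOT / "associations"
    out.mkdir(parents=True, exist_ok=True)
    clustered = cluster_heatmap(assoc, fig_path=out / "heatmap.png")
    write_results({"associations": clustered.long(), "group_tests": group_tests}, out)
    n_cells = int((clustered.q < 0.05).sum().sum())
    print(f"{n_cells} miR-phenotype cells significant at FDR < 0.05; heatmap -> {out / 'heatmap.png'}")


if __name__ == "__main__":
    main()
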