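"""Twin-aware differential expression of the simulated study.

Fits the Poisson-lognormal mixed model (random subject effect, correlated
within twin pairs) to every detected miR, Wald-tests the three pairwise
group contrasts, applies BH-FDR per comparison and writes the contrast table
(per-group mean counts, overdispersion, p/q/direction).  Finishes by checking that the planted twin-discordant miRs
are the top HRT-vs-NoHRT calls.
"""

import json
from pathlib import Path

from exomir import read_count_matrix, read_sample_table, run_de_analysis, write_results

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    study = ROOT / "simulated_study"
    counts = read_count_matrix(study / "counts.tsv")
    samples = read_sample_table(study / "samples.csv")
    truth = json.loads((study / "truth.json").read_text())

    fits, table = run_de_analysis(counts, samples)
    write_results({"contrasts": table}, ROOT / "de")
    n_sig = int((table["q"] < 0.05).sum())
    print(f"fit {len(fits)} miRs ({sum(f.converged for f in fits)} converged); "
          f"{n_sig} (miR, comparison) calls at q < 0.05")

    twin = table[table["comparison"] == "HRT_vs_NOHRT"].sort_values(["q", "p"])
    top = list(twin["mir_id"].head(len(truth["planted_mirs"])))
    print(f"planted miRs: {sorted(truth['planted_mirs'])}")
    print(f"top HRT-vs-NoHRT calls: {sorted(top)}")
    recovered = set(top) == set(truth["planted_mirs"])
    print("planted effects recovered as the top twin-contrast calls:", recovered)


if __name__ == "__main__":
    main()
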