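"""Generate the synthetic serum-exomiR study used by the downstream analyses.

Emulates the study conditions: 8 premenopausal singletons, 10 monozygotic
postmenopausal twin pairs discordant for HRT (28 samples), 241 miRs with a
heavy-tailed composition, Poisson-lognormal counts (sigma2 = 0.1, within-pair
rho = 0.5), group phenotypes at the reference population values, and a 6-target
qPCR validation plate.  Twin-discordant log-2 effects are planted in four
miRs so the differential-expression stage has ground truth to recover.

Writes counts.tsv, samples.csv, qpcr_plate.csv and truth.json under
results/simulated_study/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from exomir import (
    SimulationParams,
    StudyDesign,
    default_baseline,
    simulate_counts,
    simulate_phenotypes,
    simulate_qpcr,
    write_count_matrix,
    write_qpcr_plate,
    write_sample_table,
)

SEED = 20170214
OUT = Path(__file__).resolve().parents[1] / "results" / "simulated_study"
N_PLANTED = 4
PLANTED_EFFECT = np.log(2.0)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    design = StudyDesign()  # 8 + 10 pairs, 241 miRs
    beta_hrt = np.zeros(design.n_mirs)
    # plant the twin-discordant effect in mid-abundance miRs (ranks 20-23)
    planted_idx = np.arange(19, 19 + N_PLANTED)
    beta_hrt[planted_idx] = PLANTED_EFFECT
    params = SimulationParams(
        baseline_log_means=default_baseline(design.n_mirs),
        beta_hrt=beta_hrt,
        sigma2=0.1,
        rho=0.5,
        seed=SEED,
    )
    counts, samples = simulate_counts(design, params)
    samples = simulate_phenotypes(samples, seed=SEED)

    # 6-target validation panel, true NRQs lognormal around 1
    panel = [counts.mir_ids[i] for i in range(6)]
    rng = np.random.default_rng(SEED)
    q = pd.DataFrame(
        np.exp(rng.normal(0.0, 0.4, (len(samples.sample_ids), 6))),
        index=samples.sample_ids,
        columns=panel,
    )
    q = q.div(np.exp(np.log(q).mean(axis=1)), axis=0)
    plate = simulate_qpcr(samples, q, seed=SEED)

    write_count_matrix(counts, OUT / "counts.tsv")
    write_sample_table(samples, OUT / "samples.csv")
    write_qpcr_plate(plate, OUT / "qpcr_plate.csv")
    truth = {
        "seed": SEED,
        "planted_mirs": [counts.mir_ids[i] for i in planted_idx],
        "planted_effect_log": PLANTED_EFFECT,
        "sigma2": 0.1,
        "rho": 0.5,
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    print(f"wrote {design.n_mirs} miRs x {design.n_samples} samples to {OUT}")
    print(f"planted log-2 HRT-vs-NoHRT effects in: {truth['planted_mirs']}")


if __name__ == "__main__":
    main()
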