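"""qPCR validation pipeline: Ct filtering, spike-in dCt, calibrator RQ and
geometric-mean NRQ normalization, plus group comparison of NRQs.

Each sample's target Cts are first referenced to its cel-miR-39 spike-in
(dCt = Ct_target - Ct_spike), then to a pooled calibrator sample run across
plates (RQ = 2^-ddCt, assuming 2-fold-per-cycle chemistry).  The normalized
relative quantity divides each RQ by the sample's normalization factor NF,
the geometric mean of its RQs over expressed targets (NRQ = RQ / NF), so the
per-sample geometric mean of NRQs is 1 by construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .association import compare_groups
from .datatypes import GROUPS, SampleTable

logger = logging.getLogger(__name__)

DEFAULT_MAX_CT = 36.0


def filter_ct(plate: pd.DataFrame, max_ct: float = DEFAULT_MAX_CT) -> pd.DataFrame:
    """Keep records with Ct strictly below ``max_ct`` (default 36 cycles).

    A sample whose spike-in record is removed cannot be normalized and is
    excluded entirely (with a warning); an empty result is returned, not an
    exception, if nothing survives.
    """
    if max_ct <= 0:
        raise ValueError("max_ct must be positive")
    kept = plate[plate["ct"] < max_ct].copy()
    removed = plate[plate["ct"] >= max_ct]
    if len(removed):
        per_target = removed.groupby("target_id").size()
        logger.info("Ct filter removed %d records: %s", len(removed), per_target.to_dict())
    # samples that lost their spike-in cannot be normalized
    spike_ok = set(kept.loc[kept["is_spike"], "sample_id"])
    lost = sorted(set(kept["sample_id"]) - spike_ok)
    if lost:
        logger.warning("samples excluded (spike-in failed Ct filter): %s", lost)
        kept = kept[kept["sample_id"].isin(spike_ok)]
    if kept.empty:
        logger.warning("no records survive the Ct filter")
    return kept.reset_index(drop=True)


def compute_nrq(plate: pd.DataFrame) -> pd.DataFrame:
    """Spike-referenced, calibrator-relative, geometric-mean-normalized quantities.

    Returns one row per (sample, target): dct, rq (2^-ddCt vs the
    calibrator) and nrq (rq / per-sample geometric mean of rqs over
    expressed targets).  Targets without a calibrator value are excluded and
    logged.  The calibrator sample itself is not reported.
    """
    spikes = plate[plate["is_spike"]].set_index("sample_id")["ct"]
    targets_df = plate[~plate["is_spike"]]
    cal_ids = plate.loc[plate["is_calibrator"], "sample_id"].unique()
    if len(cal_ids) != 1:
        raise ValueError(f"need exactly one calibrator sample, found {list(cal_ids)}")
    cal = cal_ids[0]
    if cal not in spikes.index:
        raise ValueError("calibrator sample has no spike-in record")

    dct = targets_df.copy()
    dct["dct"] = dct["ct"] - spikes.reindex(dct["sample_id"]).to_numpy()
    cal_dct = dct[dct["sample_id"] == cal].set_index("target_id")["dct"]

    missing = sorted(set(dct["target_id"]) - set(cal_dct.index))
    if missing:
        logger.warning("targets without calibrator value excluded: %s", missing)
        dct = dct[~dct["target_id"].isin(missing)]

    dct = dct[dct["sample_id"] != cal].copy()
    dct["rq"] = 2.0 ** -(dct["dct"] - cal_dct.reindex(dct["target_id"]).to_numpy())

    nf = dct.groupby("sample_id")["rq"].apply(lambda r: float(gmean(r)))
    singles = nf.index[dct.groupby("sample_id").size() == 1]
    if len(singles):
        logger.warning("samples with a single expressed target (NRQ forced to 1): %s", list(singles))
    dct["nrq"] = dct["rq"] / nf.reindex(dct["sample_id"]).to_numpy()
    out = dct[["sample_id", "target_id", "dct", "rq", "nrq"]].reset_index(drop=True)
    return out


def compare_nrq_groups(
    nrq: pd.DataFrame, samples: SampleTable, alpha_normality: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-target three-way group comparisons of NRQs plus group summaries.

    Returns (tests, summary): the Shapiro-gated test table per target, and
    per-group arithmetic mean +/- SD of NRQs for plotting.  Targets with a
    group below two observations are skipped.
    """
    rows = []
    summaries = []
    wide = nrq.pivot(index="sample_id", columns="target_id", values="nrq")
    for target in wide.columns:
        vals = wide[target]
        by_group = {
            g: vals.reindex(samples.group_samples(g)).dropna() for g in GROUPS
        }
        for g, v in by_group.items():
            summaries.append(
                {"target_id": target, "group": g, "n": len(v),
                 "mean_nrq": v.mean() if len(v) else np.nan,
                 "sd_nrq": v.std(ddof=1) if len(v) > 1 else np.nan}
            )
        if min(len(v) for v in by_group.values()) < 2:
            logger.warning("target %s skipped: a group has < 2 NRQ values", target)
            continue
        try:
            results = compare_groups(vals, samples, alpha_normality, variable=target)
        except ValueError as exc:
            logger.warning("target %s skipped: %s", target, exc)
            continue
        rows.extend(vars(r) for r in results)
    tests = pd.DataFrame(rows, columns=["variable", "comparison", "test_used", "statistic", "p"])
    return tests, pd.DataFrame(summaries)
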