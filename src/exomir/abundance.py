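"""Relative exomiR content profiling: per-miR fractions of total reads.

The serum exomiR pool is extremely skewed — a handful of miRs (led by
miR-486-5p and miR-92a-3p in serum) carry the bulk of all reads — so the
profile is summarised as each miR's fraction of the pooled read total and
the coverage of the top-ranked miRs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CountMatrix


def relative_abundance(counts: CountMatrix, per_sample_mean: bool = False) -> pd.DataFrame:
    """Per-miR fraction of total reads, ranked by descending fraction.

    By default fractions are computed on pooled raw counts across all
    samples; ``per_sample_mean=True`` instead averages each sample's
    within-sample fractions (both readings of a whole-cohort content
    profile).  Rank ties break lexicographically by mir_id.
    """
    df = counts.counts
    if int(df.to_numpy().sum()) == 0:
        raise ValueError("all-zero count matrix has no abundance profile")
    if per_sample_mean:
        frac_by_sample = df / df.sum(axis=0)
        frac = frac_by_sample.mean(axis=1)
    else:
        totals = df.sum(axis=1)
        frac = totals / totals.sum()
    prof = pd.DataFrame({"mir_id": frac.index, "fraction": frac.to_numpy(float)})
    prof = prof.sort_values(["fraction", "mir_id"], ascending=[False, True], kind="mergesort")
    prof["rank"] = np.arange(1, len(prof) + 1)
    return prof.reset_index(drop=True)


def top_n_coverage(profile: pd.DataFrame, mir_ids=None, n: int | None = None) -> float:
    """Percent of total reads covered by the named miRs (or the top n)."""
    if (mir_ids is None) == (n is None):
        raise ValueError("give exactly one of mir_ids or n")
    if n is not None:
        sel = profile.nsmallest(n, "rank")
    else:
        known = set(profile["mir_id"])
        missing = [m for m in mir_ids if m not in known]
        if missing:
            raise KeyError(f"unknown mir_ids: {missing}")
        sel = profile[profile["mir_id"].isin(list(mir_ids))]
    return float(sel["fraction"].sum() * 100.0)


def detected_mirs(counts: CountMatrix, min_total: int = 1) -> list[str]:
    """miRs whose total read count reaches ``min_total``, sorted by id."""
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    totals = counts.counts.sum(axis=1)
    return sorted(totals.index[totals >= min_total])
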