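"""Core containers for the exomiR study: count matrices and sample metadata.

The study design is three groups of women — premenopausal singletons (PRE)
and postmenopausal monozygotic twin pairs discordant for estrogen-based
hormone replacement therapy (POST_NOHRT / POST_HRT).  Twin pairing is
carried in the sample table and drives both the paired group tests and the
within-pair random-effect correlation of the count model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_PRE = "PRE"
GROUP_NOHRT = "POST_NOHRT"
GROUP_HRT = "POST_HRT"
GROUPS = (GROUP_PRE, GROUP_NOHRT, GROUP_HRT)

#: canonical names of the three pairwise comparisons; the first-named group
#: is the one whose direction arrow is reported.
COMPARISONS = ("NOHRT_vs_PRE", "HRT_vs_PRE", "HRT_vs_NOHRT")

_GROUP_ALIASES = {g.lower(): g for g in GROUPS}
# tolerate common spellings seen in hand-edited metadata
_GROUP_ALIASES.update(
    {
        "pre": GROUP_PRE,
        "premenopausal": GROUP_PRE,
        "post_nohrt": GROUP_NOHRT,
        "nohrt": GROUP_NOHRT,
        "no_hrt": GROUP_NOHRT,
        "post_hrt": GROUP_HRT,
        "hrt": GROUP_HRT,
    }
)


class FormatError(ValueError):
    """A file failed structural validation (bad values, duplicates, missing cells)."""


class DesignError(ValueError):
    """Sample metadata violates the study design (pairing/group invariants)."""


def canonical_group(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _GROUP_ALIASES:
        raise DesignError(
            f"unknown group label {label!r}; expected one of {GROUPS} (case-insensitive)"
        )
    return _GROUP_ALIASES[key]


@dataclass
class CountMatrix:
    """Nonnegative integer read counts, miRs (rows) x samples (columns)."""

    counts: pd.DataFrame  # index = mir_id, columns = sample_id, integer dtype

    def __post_init__(self) -> None:
        self.validate()

    @property
    def mir_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def validate(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate mir_id rows: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample_id columns: {dupes}")
        if df.isna().any().any():
            r, c = next(zip(*np.where(df.isna())))
            raise FormatError(
                f"missing count at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise FormatError("counts must have integer dtype")
        if (vals < 0).any():
            raise FormatError("negative counts are not allowed")

    def subset(self, mir_ids=None, sample_ids=None) -> "CountMatrix":
        df = self.counts
        if mir_ids is not None:
            missing = [m for m in mir_ids if m not in df.index]
            if missing:
                raise KeyError(f"unknown mir_ids: {missing}")
            df = df.loc[list(mir_ids)]
        if sample_ids is not None:
            df = df[list(sample_ids)]
        return CountMatrix(df.copy())


@dataclass
class SampleTable:
    """Per-sample metadata: group, twin-pair id and any phenotype columns.

    pair_id is null exactly for PRE singletons; each non-null pair_id occurs
    twice, once in each postmenopausal group.
    """

    table: pd.DataFrame = field()  # columns: sample_id, group, pair_id, phenotypes...

    REQUIRED = ("sample_id", "group", "pair_id")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"sample table missing required column {col!r}")
        df["group"] = [canonical_group(g) for g in df["group"]]
        self.table = df.reset_index(drop=True)
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def phenotype_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.REQUIRED]

    def group_samples(self, group: str) -> list[str]:
        g = canonical_group(group)
        return list(self.table.loc[self.table["group"] == g, "sample_id"])

    def pairs(self) -> pd.DataFrame:
        """One row per twin pair: pair_id, nohrt sample, hrt sample."""
        df = self.table
        paired = df[df["pair_id"].notna()]
        rows = []
        for pid, grp in paired.groupby("pair_id"):
            by_group = dict(zip(grp["group"], grp["sample_id"]))
            rows.append(
                {
                    "pair_id": pid,
                    GROUP_NOHRT: by_group[GROUP_NOHRT],
                    GROUP_HRT: by_group[GROUP_HRT],
                }
            )
        return pd.DataFrame(rows, columns=["pair_id", GROUP_NOHRT, GROUP_HRT])

    def validate(self) -> None:
        df = self.table
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        pre_with_pair = df[(df["group"] == GROUP_PRE) & df["pair_id"].notna()]
        if len(pre_with_pair):
            raise DesignError(
                f"PRE samples must be singletons; offending samples: "
                f"{pre_with_pair['sample_id'].tolist()}"
            )
        post = df[df["group"] != GROUP_PRE]
        if post["pair_id"].isna().any():
            orphans = post.loc[post["pair_id"].isna(), "sample_id"].tolist()
            raise DesignError(f"postmenopausal samples without pair_id: {orphans}")
        for pid, grp in post.groupby("pair_id"):
            groups = sorted(grp["group"])
            if groups != sorted([GROUP_NOHRT, GROUP_HRT]):
                raise DesignError(
                    f"pair {pid!r} must have exactly one {GROUP_NOHRT} and one "
                    f"{GROUP_HRT} member; found {list(grp['group'])}"
                )
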