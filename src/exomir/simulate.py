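"""Synthetic exomiR study generator.

Emulates the study conditions downstream modules are built for: 8 unrelated
premenopausal women plus 10 monozygotic postmenopausal twin pairs discordant
for hormone replacement therapy (28 serum samples), ~241 detected miRs with
a strongly skewed composition (a handful of miRs dominating total reads),
Poisson read counts whose log-rate carries a normally distributed per-subject
random effect correlated within twin pairs, group-specific log fold-changes,
and optional library-size variation.

Every stage of the pipeline can therefore be exercised against known ground
truth: the generator returns (or writes) the true baseline log-means, group
effects, random-effect variance and twin correlation alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import GROUP_HRT, GROUP_NOHRT, GROUP_PRE, CountMatrix, SampleTable

# stream labels -> spawn keys, so one global seed yields independent
# substreams per operation
_STREAMS = {"counts": 0, "phenotypes": 1, "qpcr": 2, "params": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class StudyDesign:
    """Sample layout: PRE singletons plus discordant postmenopausal twin pairs."""

    n_singletons: int = 8
    n_pairs: int = 10
    n_mirs: int = 241
    library_sizes: np.ndarray | None = None  # per-sample positive scale factors

    def __post_init__(self) -> None:
        if self.n_mirs < 1:
            raise ValueError("n_mirs must be >= 1")
        if self.n_singletons < 0 or self.n_pairs < 0:
            raise ValueError("sample counts must be nonnegative")
        if self.library_sizes is not None:
            ls = np.asarray(self.library_sizes, dtype=float)
            if ls.shape != (self.n_samples,):
                raise ValueError(f"library_sizes must have length {self.n_samples}")
            if (ls <= 0).any():
                raise ValueError("library sizes must be positive")
            self.library_sizes = ls

    @property
    def n_samples(self) -> int:
        return self.n_singletons + 2 * self.n_pairs


@dataclass
class SimulationParams:
    """True per-miR parameters of the Poisson-lognormal twin model.

    ``baseline_log_means`` are natural-log rates for the PRE reference group;
    ``beta_nohrt``/``beta_hrt`` are group log fold-changes relative to PRE;
    ``sigma2`` is the variance of the per-subject log-normal random effect
    (the model's overdispersion) and ``rho`` its correlation within a twin
    pair.  Scalars broadcast over miRs.
    """

    baseline_log_means: np.ndarray
    beta_nohrt: np.ndarray | float = 0.0
    beta_hrt: np.ndarray | float = 0.0
    sigma2: np.ndarray | float = 0.1
    rho: np.ndarray | float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline_log_means = np.atleast_1d(np.asarray(self.baseline_log_means, float))
        if not np.isfinite(self.baseline_log_means).all():
            raise ValueError("baseline log-means must be finite")
        n = len(self.baseline_log_means)
        self.beta_nohrt = np.broadcast_to(np.asarray(self.beta_nohrt, float), (n,)).copy()
        self.beta_hrt = np.broadcast_to(np.asarray(self.beta_hrt, float), (n,)).copy()
        self.sigma2 = np.broadcast_to(np.asarray(self.sigma2, float), (n,)).copy()
        self.rho = np.broadcast_to(np.asarray(self.rho, float), (n,)).copy()
        if (self.sigma2 < 0).any():
            raise ValueError("sigma2 must be nonnegative")
        if (np.abs(self.rho) >= 1).any():
            raise ValueError("|rho| must be < 1")

    @property
    def n_mirs(self) -> int:
        return len(self.baseline_log_means)


def composition_exponent(n_mirs: int = 241, top_n: int = 6, top_share: float = 0.846) -> float:
    """Power-law exponent a such that fractions ~ rank^-a give the requested
    top-n share of total reads (84.6% over the top 6 of 241 by default)."""
    ranks = np.arange(1, n_mirs + 1)

    def share(a):
        f = ranks ** (-a)
        return f[:top_n].sum() / f.sum() - top_share

    return brentq(share, 0.1, 10.0)


def default_baseline(
    n_mirs: int = 241,
    total_reads: float = 5e5,
    composition_skew: float | None = None,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Baseline log-means with a serum-like heavy-tailed composition.

    ``composition_skew`` is the power-law exponent of abundance vs rank; by
    default it is calibrated so the top 6 miRs carry ~84.6% of reads.
    Optional lognormal jitter perturbs the smooth profile.
    """
    if composition_skew is not None:
        a = composition_skew
    elif n_mirs > 12:
        a = composition_exponent(n_mirs)
    else:
        # too few features to calibrate a top-6 share; reuse the study-scale
        # exponent
        a = composition_exponent(241)
    ranks = np.arange(1, n_mirs + 1)
    frac = ranks ** (-a)
    frac = frac / frac.sum()
    mu = np.log(total_reads * frac)
    if jitter_sd > 0:
        mu = mu + _rng(seed, "params").normal(0.0, jitter_sd, size=n_mirs)
    return mu


def default_params(n_mirs: int = 241, seed: int = 0, **kwargs) -> SimulationParams:
    """Study-scale defaults: calibrated composition, sigma2=0.1, rho=0.5."""
    mu = default_baseline(n_mirs=n_mirs, seed=seed)
    return SimulationParams(baseline_log_means=mu, seed=seed, **kwargs)


def build_sample_table(design: StudyDesign) -> SampleTable:
    """Deterministic sample metadata for a design (no phenotypes yet)."""
    rows = []
    for i in range(design.n_singletons):
        rows.append({"sample_id": f"PRE{i + 1:02d}", "group": GROUP_PRE, "pair_id": None})
    for i in range(design.n_pairs):
        pid = f"TW{i + 1:02d}"
        rows.append({"sample_id": f"NOHRT{i + 1:02d}", "group": GROUP_NOHRT, "pair_id": pid})
        rows.append({"sample_id": f"HRT{i + 1:02d}", "group": GROUP_HRT, "pair_id": pid})
    return SampleTable(pd.DataFrame(rows, columns=["sample_id", "group", "pair_id"]))


def simulate_counts(
    design: StudyDesign, params: SimulationParams
) -> tuple[CountMatrix, SampleTable]:
    """Draw a count matrix from the Poisson-lognormal twin model.

    For miR g and subject i, y_gi ~ Poisson(exp(eta_gi)) with
    eta_gi = mu_g + beta_g,group(i) + u_gi + log(library_size_i); the random
    effects of a twin pair are jointly normal with variance sigma2_g and
    correlation rho_g, singleton effects are independent N(0, sigma2_g).
    Reproducible given ``params.seed``.
    """
    if params.n_mirs != design.n_mirs:
        raise ValueError(
            f"params cover {params.n_mirs} miRs but design has {design.n_mirs}"
        )
    rng = _rng(params.seed, "counts")
    st = build_sample_table(design)
    G = design.n_mirs
    ns, npair = design.n_singletons, design.n_pairs

    sig = np.sqrt(params.sigma2)[:, None]
    u_single = rng.standard_normal((G, ns)) * sig
    # pair effects via Cholesky of [[1, rho], [rho, 1]]
    z1 = rng.standard_normal((G, npair))
    z2 = rng.standard_normal((G, npair))
    rho = params.rho[:, None]
    u_a = sig * z1
    u_b = sig * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)

    mu = params.baseline_log_means[:, None]
    eta_single = mu + u_single
    eta_a = mu + params.beta_nohrt[:, None] + u_a
    eta_b = mu + params.beta_hrt[:, None] + u_b

    # column order matches build_sample_table: PRE..., then NOHRT/HRT interleaved
    eta = np.empty((G, design.n_samples))
    eta[:, :ns] = eta_single
    eta[:, ns::2] = eta_a
    eta[:, ns + 1 :: 2] = eta_b
    if design.library_sizes is not None:
        eta = eta + np.log(design.library_sizes)[None, :]

    y = rng.poisson(np.exp(eta))
    mir_ids = [f"miR-sim-{i + 1:04d}" for i in range(G)]
    cm = CountMatrix(pd.DataFrame(y, index=pd.Index(mir_ids, name="mir_id"), columns=st.sample_ids))
    return cm, st


# Group-specific (mean, sd) for PRE / POST_NOHRT / POST_HRT, on the scale and
# in the units the study population was characterised with.  These anchor the
# phenotype generator's defaults.
PHENOTYPE_REFERENCE: dict[str, dict[str, tuple[float, float]]] = {
    "age_yrs": {GROUP_PRE: (32.0, 1.6), GROUP_NOHRT: (57.5, 2.0), GROUP_HRT: (57.5, 2.0)},
    "bmi": {GROUP_PRE: (25.9, 4.5), GROUP_NOHRT: (28.6, 6.8), GROUP_HRT: (25.7, 4.0)},
    "waist_cm": {GROUP_PRE: (86.4, 10.4), GROUP_NOHRT: (104.7, 9.6), GROUP_HRT: (100.9, 6.4)},
    "fat_pct": {GROUP_PRE: (29.7, 7.0), GROUP_NOHRT: (35.3, 9.3), GROUP_HRT: (30.5, 7.5)},
    "hscrp_mg_l": {GROUP_PRE: (0.88, 1.1), GROUP_NOHRT: (1.53, 0.94), GROUP_HRT: (1.09, 0.95)},
    "il6_pg_ml": {GROUP_PRE: (1.05, 0.70), GROUP_NOHRT: (1.77, 1.29), GROUP_HRT: (1.39, 0.71)},
    "tnfa_pg_ml": {GROUP_PRE: (6.1, 1.6), GROUP_NOHRT: (10.5, 2.3), GROUP_HRT: (10.7, 4.8)},
    "chol_mmol_l": {GROUP_PRE: (4.7, 0.8), GROUP_NOHRT: (5.3, 0.4), GROUP_HRT: (5.3, 0.7)},
    "ldl_mmol_l": {GROUP_PRE: (2.7, 0.8), GROUP_NOHRT: (3.1, 0.4), GROUP_HRT: (3.1, 0.8)},
    "hdl_mmol_l": {GROUP_PRE: (1.6, 0.4), GROUP_NOHRT: (1.6, 0.4), GROUP_HRT: (1.6, 0.5)},
    "trigly_mmol_l": {GROUP_PRE: (0.8, 0.2), GROUP_NOHRT: (1.2, 0.5), GROUP_HRT: (1.2, 1.0)},
    "adiponectin_ng_ml": {GROUP_PRE: (7432, 3606), GROUP_NOHRT: (9382, 5273), GROUP_HRT: (10267, 5350)},
    "leptin_pg_ml": {GROUP_PRE: (23225, 10977), GROUP_NOHRT: (18571, 13705), GROUP_HRT: (12483, 8672)},
    "resistin_ng_ml": {GROUP_PRE: (9.4, 2.0), GROUP_NOHRT: (10.2, 1.2), GROUP_HRT: (9.7, 1.4)},
    "insulin_mmol_l": {GROUP_PRE: (5.3, 3.3), GROUP_NOHRT: (8.0, 4.5), GROUP_HRT: (6.2, 3.6)},
    "glucose_mmol_l": {GROUP_PRE: (4.2, 0.4), GROUP_NOHRT: (5.2, 0.7), GROUP_HRT: (5.0, 0.7)},
    "e2_pmol_l": {GROUP_PRE: (496.5, 311.9), GROUP_NOHRT: (34.8, 28.4), GROUP_HRT: (183.0, 211.3)},
    "fsh_iu_l": {GROUP_PRE: (6.22, 2.85), GROUP_NOHRT: (83.7, 32.7), GROUP_HRT: (57.0, 31.2)},
}


#: analytes whose population distributions are classically right-skewed
#: (hormones, adipokines, acute-phase and inflammatory markers); these are
#: drawn moment-matched lognormal rather than normal
SKEWED_PHENOTYPES = {
    "e2_pmol_l",
    "e1_pmol_l",
    "hscrp_mg_l",
    "il6_pg_ml",
    "leptin_pg_ml",
    "adiponectin_ng_ml",
    "insulin_mmol_l",
    "trigly_mmol_l",
}


def simulate_phenotypes(
    sample_table: SampleTable,
    effect_spec: dict | None = None,
    seed: int = 0,
    counts: CountMatrix | None = None,
    couplings: dict[str, tuple[str, float, float]] | None = None,
    pair_correlation: float = 0.5,
    skewed: set[str] | None = None,
) -> SampleTable:
    """Attach phenotype columns drawn from group-specific distributions.

    ``effect_spec`` maps phenotype name -> {group: (mean, sd)}; the default is
    the study-population reference panel.  Values are normal except for the
    ``skewed`` analytes, which are moment-matched lognormal (serum hormones
    and inflammatory markers are right-skewed in practice).  Monozygotic twin
    phenotypes share a latent component: ``pair_correlation`` is the
    within-pair correlation of the standardized latent draws.

    ``couplings`` optionally defines a phenotype as a monotone function of a
    miR's counts, value = slope * log1p(count) + N(0, noise_sd), creating
    known associations for testing the correlation stage; entries are
    (mir_id, slope, noise_sd).
    """
    spec = effect_spec if effect_spec is not None else PHENOTYPE_REFERENCE
    skewed = SKEWED_PHENOTYPES if skewed is None else skewed
    couplings = couplings or {}
    if not -1.0 < pair_correlation < 1.0:
        raise ValueError("|pair_correlation| must be < 1")
    rng = _rng(seed, "phenotypes")
    df = sample_table.table.copy()
    groups = df["group"].to_numpy()
    pair_ids = df["pair_id"].to_numpy(object)

    for name in couplings:
        if counts is None:
            raise ValueError("couplings require the count matrix")

    def _latent():
        """Standard-normal draws with within-pair correlation."""
        z = rng.standard_normal(len(df))
        shared = {}
        for pid in pd.unique(pair_ids[pd.notna(pair_ids)]):
            shared[pid] = rng.standard_normal()
        r = pair_correlation
        for i, pid in enumerate(pair_ids):
            if pd.notna(pid):
                z[i] = np.sqrt(r) * shared[pid] + np.sqrt(1 - r) * z[i]
        return z

    for name, by_group in spec.items():
        unknown = set(by_group) - {GROUP_PRE, GROUP_NOHRT, GROUP_HRT}
        if unknown:
            raise ValueError(f"effect_spec for {name!r} has unknown groups {unknown}")
        z = _latent()
        vals = np.empty(len(df))
        for g, (mean, sd) in by_group.items():
            mask = groups == g
            if name in skewed and mean > 0:
                # lognormal with matching mean and sd
                s2 = np.log1p((sd / mean) ** 2)
                mu = np.log(mean) - s2 / 2
                vals[mask] = np.exp(mu + np.sqrt(s2) * z[mask])
            else:
                vals[mask] = mean + sd * z[mask]
        df[name] = vals

    for name, (mir_id, slope, noise_sd) in couplings.items():
        y = counts.counts.loc[mir_id, df["sample_id"]].to_numpy(float)
        df[name] = slope * np.log1p(y) + rng.normal(0.0, noise_sd, size=len(df))

    return SampleTable(df)


def simulate_qpcr(
    sample_table: SampleTable,
    true_nrq: pd.DataFrame,
    noise_sd: float = 0.15,
    seed: int = 0,
    spike_ct_mean: float = 25.1,
    spike_ct_sd: float = 1.0,
    base_dct: float = 5.0,
    spike_target_id: str = "cel-miR-39",
    calibrator_id: str = "CALIBRATOR",
) -> pd.DataFrame:
    """Emit a qPCR plate consistent with 2-fold-per-cycle chemistry.

    ``true_nrq`` is a samples x targets table of positive relative
    quantities.  Each target's Ct is the sample's spike-in Ct plus a
    target-specific offset minus log2(quantity), plus Gaussian Ct noise.
    One calibrator sample (all quantities 1) and one spike-in row per sample
    are included.  With ``noise_sd=0`` the downstream NRQ pipeline recovers
    ``true_nrq`` exactly up to the per-sample geometric-mean rescaling.
    """
    if (true_nrq.to_numpy(float) <= 0).any():
        raise ValueError("true relative quantities must be positive")
    rng = _rng(seed, "qpcr")
    targets = list(true_nrq.columns)
    # per-target base offsets above the spike-in Ct
    offsets = base_dct + 0.5 * np.arange(len(targets))

    rows = []
    all_samples = list(true_nrq.index) + [calibrator_id]
    for s in all_samples:
        spike_ct = rng.normal(spike_ct_mean, spike_ct_sd)
        rows.append(
            {"sample_id": s, "target_id": spike_target_id, "ct": spike_ct,
             "is_spike": True, "is_calibrator": s == calibrator_id}
        )
        for t, off in zip(targets, offsets):
            q = 1.0 if s == calibrator_id else float(true_nrq.loc[s, t])
            ct = spike_ct + off - np.log2(q) + rng.normal(0.0, noise_sd)
            rows.append(
                {"sample_id": s, "target_id": t, "ct": ct,
                 "is_spike": False, "is_calibrator": s == calibrator_id}
            )
    return pd.DataFrame(rows, columns=["sample_id", "target_id", "ct", "is_spike", "is_calibrator"])
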