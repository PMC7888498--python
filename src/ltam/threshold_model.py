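"""Multi-trait linear-threshold animal model fitted by Gibbs sampling.

The model is y = Xb + Za + e for a fixed trait vector (by default NBA1,
NBA2, NBA3 continuous and STAY14 binary), where y holds the observed litter
sizes and, for the binary trait, an unobservable Gaussian liability with
threshold 0; b are contemporary-group effects plus an AFF covariate per
trait; a ~ N(0, A x G) are additive genetic effects over the whole
pedigree; e ~ N(0, I x R).  Because the liability scale of a binary trait
is not identified, its residual variance is pinned to exactly 1 in every
cycle and the threshold is fixed at 0.

Sampling scheme (single-site Gibbs with full data augmentation):

1. liabilities for records with an observed STAY14 category are drawn from
   their residual conditional (given the other traits' current residuals
   under R), truncated to the side of 0 that matches the category;
2. missing continuous cells (litters never farrowed because the sow was
   culled) are augmented with unconstrained conditional-normal draws so
   every record becomes complete;
3. location effects: contemporary-group levels (jointly within a factor —
   levels share no records, so this equals single-site updating) and the
   AFF regression per trait, flat priors;
4. animal effects animal-by-animal using the sparse A inverse (numba);
5. G from its inverted-Wishart full conditional with scale a' A^-1 a plus
   the prior scale;
6. R under the pinned-variance constraint: the continuous residual block
   from its marginal inverted Wishart, then the regression of the liability
   residual on the continuous residuals from its normal conditional, and
   the covariances rebuilt with the liability variance held at exactly 1
   (never post-hoc rescaling, which would change the stationary law).

Priors: location effects of continuous traits are flat; liability-scale
location effects carry a diffuse proper normal prior (see
:func:`sample_location` for why the flat convention is untenable there);
G and the free part of R default to minimally informative inverted
Wisharts (df = dimension + 1, scale 0.01 I), with the flat convention
available by passing df 0.  Chains start from a moments-based split of
the empirical phenotypic covariance with the animal effects at their BLUP
solution, and hold (G, R) fixed for a short warm-up inside the burn-in;
see the methods note for the mixing rationale.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import ndtr, ndtri
from scipy.stats import invwishart
from sklearn.base import BaseEstimator

from .errors import NumericalError, ValidationError
from .pedigree import (
    RenumberedPedigree, PedigreeRecord, renumber, compute_inbreeding,
    build_a_inverse,
)
from ._kernels import animal_sweep

logger = logging.getLogger(__name__)

_EPS_TAIL = 1e-14


@dataclass(frozen=True)
class TraitSpec:
    """One analysed trait: its column name, whether it is a Gaussian
    observation or a thresholded binary one, and whether the AFF covariate
    applies to it (it does for all four traits by default)."""

    name: str
    kind: str = "continuous"
    use_aff: bool = True

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValidationError(f"unknown trait kind {self.kind!r}")


DEFAULT_TRAITS = (
    TraitSpec("nba1"),
    TraitSpec("nba2"),
    TraitSpec("nba3"),
    TraitSpec("stay14", kind="binary"),
)


@dataclass
class ChainConfig:
    """Gibbs chain protocol and priors.

    Defaults mirror the single-chain protocol used for this model family:
    250,000 cycles, 50,000 burn-in, thinning 50 — exactly 4,000 stored
    samples.  nu_g/s0_g and nu_r/s0_r are inverted-Wishart prior degrees of
    freedom and scale for G and the free part of R; zero means flat.
    """

    n_cycles: int = 250_000
    burn_in: int = 50_000
    thin: int = 50
    seed: int = 0
    nu_g: float | None = None
    s0_g: np.ndarray | None = None
    nu_r: float | None = None
    s0_r: np.ndarray | None = None
    zero_resid_cov_binary: bool = False
    beta_prior_var_binary: float | None = 1.0
    init_corr_g: float | None = None
    init_empirical_corr: bool = True
    blup_start: bool = True
    fixed_var_warmup: int = 500
    store_location: bool = False
    validate_every: int = 0

    def validate(self) -> None:
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if not 0 <= self.burn_in < self.n_cycles:
            raise ValidationError("burn_in must satisfy 0 <= burn_in < n_cycles")
        if (self.n_cycles - self.burn_in) % self.thin != 0:
            raise ValidationError(
                "(n_cycles - burn_in) must be divisible by thin for an exact "
                "stored-sample count"
            )

    @property
    def n_stored(self) -> int:
        self.validate()
        return (self.n_cycles - self.burn_in) // self.thin

    @property
    def effective_warmup(self) -> int:
        """Fixed-variance warm-up cycles, clamped to half the burn-in so
        short exploratory chains remain valid."""
        return min(self.fixed_var_warmup, self.burn_in // 2)


@dataclass
class ModelMatrices:
    """Incidence structure of the analysis table.

    Fixed effects are encoded per trait as a contemporary-group level
    index per record plus a centred AFF covariate; Z is the record ->
    pedigree-code map.  ``obs`` masks observed cells; for the binary trait
    the observed value is the category in ``ybin`` (-1 for missing).

    The binary trait may use a coarser CG coding than the continuous
    traits: levels in which its observed values are constant (or absent)
    are pooled, see :func:`build_matrices`."""

    traits: tuple[TraitSpec, ...]
    y: np.ndarray                 # (nrec, T), NaN where unobserved
    obs: np.ndarray               # (nrec, T) bool
    ybin: np.ndarray              # (nrec,) int8 per binary trait, -1 missing
    cg_idx: np.ndarray            # (T, nrec) int64, per-trait level index
    cg_labels: list[list[str]]    # per-trait level labels
    aff: np.ndarray               # (nrec,) centred covariate
    aff_mean: float
    rec_animal: np.ndarray | None  # (nrec,) 0-based pedigree index, or None
    n_animals: int
    sows: list[str]

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def binary_index(self) -> int | None:
        idx = [t for t, ts in enumerate(self.traits) if ts.kind == "binary"]
        if len(idx) > 1:
            raise ValidationError("at most one binary trait is supported")
        return idx[0] if idx else None


def build_matrices(
    records: pd.DataFrame,
    ped: RenumberedPedigree | None,
    traits: tuple[TraitSpec, ...] = DEFAULT_TRAITS,
    merge_extreme_binary_groups: bool = True,
) -> ModelMatrices:
    """Assemble the incidence structure from an analysis table.

    ``records`` needs columns ``sow``, ``cg``, one column per trait name,
    and ``aff`` if any trait uses the covariate.  Every sow must be present
    in the pedigree when one is given.

    With flat priors on the contemporary-group effects, a group whose
    observed binary values all fall in one category (or that has none at
    all) leaves that group's liability-scale effect without a finite
    maximum — the extreme-category-subclass problem of threshold models —
    and its unbounded drift destabilises the whole chain.  The standard
    remedy is a data edit; here, by default, such levels are pooled into a
    single merged level of the binary trait's own CG coding (the
    continuous traits keep the full-resolution coding), and the pool is
    merged into the largest regular level if it is itself still extreme.
    """
    traits = tuple(traits)
    for ts in traits:
        if ts.name not in records.columns:
            raise ValidationError(f"analysis table lacks trait column {ts.name!r}")
    nrec = len(records)
    T = len(traits)
    y = records[[ts.name for ts in traits]].to_numpy(dtype=float)
    obs = ~np.isnan(y)
    ybin = np.full(nrec, -1, dtype=np.int8)
    for t, ts in enumerate(traits):
        if ts.kind == "binary":
            col = y[:, t]
            bad = ~np.isnan(col) & ~np.isin(col, (0.0, 1.0))
            if bad.any():
                raise ValidationError(
                    f"binary trait {ts.name!r} has values outside {{0,1}}"
                )
            ybin = np.where(np.isnan(col), -1, col).astype(np.int8)
    cg_cat = pd.Categorical(records["cg"].astype(str))
    base_idx = np.asarray(cg_cat.codes, dtype=np.int64)
    base_labels = [str(c) for c in cg_cat.categories]
    cg_idx = np.tile(base_idx, (T, 1))
    cg_labels: list[list[str]] = [list(base_labels) for _ in range(T)]
    if merge_extreme_binary_groups and (ybin >= 0).any():
        t_bin = next(t for t, ts in enumerate(traits) if ts.kind == "binary")
        idx_b, labels_b, n_merged = _merge_extreme_levels(
            base_idx, base_labels, ybin
        )
        cg_idx[t_bin] = idx_b
        cg_labels[t_bin] = labels_b
        if n_merged:
            logger.warning(
                "pooled %d extreme-category contemporary-group levels for "
                "the binary trait (single-category levels leave the group "
                "effect unidentified under a flat prior)", n_merged,
            )
    if any(ts.use_aff for ts in traits):
        if "aff" not in records.columns:
            raise ValidationError("analysis table lacks 'aff' column")
        aff_raw = records["aff"].to_numpy(dtype=float)
        aff_mean = float(np.mean(aff_raw))
        aff = aff_raw - aff_mean
    else:
        aff = np.zeros(nrec)
        aff_mean = 0.0
    sows = [str(s) for s in records["sow"]]
    if ped is not None:
        missing = [s for s in sows if s not in ped.code_of]
        if missing:
            raise ValidationError(
                f"sows absent from pedigree: {missing[:10]}"
            )
        rec_animal = np.array([ped.code_of[s] - 1 for s in sows], dtype=np.int64)
        n_animals = ped.n
    else:
        rec_animal = None
        n_animals = 0
    return ModelMatrices(
        traits=traits, y=y, obs=obs, ybin=ybin, cg_idx=cg_idx,
        cg_labels=cg_labels, aff=aff,
        aff_mean=aff_mean, rec_animal=rec_animal, n_animals=n_animals,
        sows=sows,
    )


def _merge_extreme_levels(base_idx: np.ndarray, base_labels: list[str],
                          ybin: np.ndarray):
    """Pool CG levels whose observed binary values are constant or absent.

    Returns a renumbered level index, the merged labels, and the number of
    pooled levels.  If the pool itself is still single-category it is
    merged into the largest level that has both categories.
    """
    n_levels = len(base_labels)
    keep, pooled = [], []
    for level in range(n_levels):
        vals = ybin[base_idx == level]
        vals = vals[vals >= 0]
        if vals.size and vals.min() != vals.max():
            keep.append(level)
        else:
            pooled.append(level)
    if not pooled:
        return base_idx.copy(), list(base_labels), 0
    if not keep:
        # nothing regular to anchor on: collapse everything into one level
        return (np.zeros_like(base_idx), ["_pooled"], n_levels)
    mapping = np.empty(n_levels, dtype=np.int64)
    for new, old in enumerate(keep):
        mapping[old] = new
    pool_code = len(keep)
    for old in pooled:
        mapping[old] = pool_code
    idx = mapping[base_idx]
    labels = [base_labels[old] for old in keep] + ["_pooled"]
    pool_vals = ybin[idx == pool_code]
    pool_vals = pool_vals[pool_vals >= 0]
    if pool_vals.size == 0 or pool_vals.min() == pool_vals.max():
        # merge the pool into the largest regular level
        sizes = np.bincount(idx[idx < pool_code], minlength=pool_code)
        target = int(np.argmax(sizes))
        idx = np.where(idx == pool_code, target, idx)
        labels = labels[:-1]
    return idx, labels, len(pooled)


# ---------------------------------------------------------------------------
# conditional-normal helpers (shared by the vectorised sweeps and the
# per-record operations used in tests)

def conditional_residual(Rinv: np.ndarray, t: int, e_row: np.ndarray):
    """Mean and SD of residual t given the other residuals of one record,
    from the residual precision matrix."""
    prec = Rinv[t, t]
    if prec <= 0:
        raise NumericalError("residual precision not positive (R not PD)")
    others = Rinv[t] @ e_row - Rinv[t, t] * e_row[t]
    return -others / prec, 1.0 / np.sqrt(prec)


def truncated_normal(rng, mean, sd, lower=None, upper=None):
    """Vectorised one-sided truncated normal via the inverse CDF.

    Tail draws are clamped to the truncation side so that category
    consistency is exact even when the bound sits many SDs from the mean.
    """
    mean = np.asarray(mean, dtype=float)
    u = rng.random(mean.shape)
    if lower is not None:
        alpha = (np.asarray(lower) - mean) / sd
        p = ndtr(alpha) + u * (1.0 - ndtr(alpha))
        x = mean + sd * ndtri(np.clip(p, _EPS_TAIL, 1 - _EPS_TAIL))
        return np.maximum(x, np.asarray(lower) + 1e-12 * sd)
    alpha = (np.asarray(upper) - mean) / sd
    p = u * ndtr(alpha)
    x = mean + sd * ndtri(np.clip(p, _EPS_TAIL, 1 - _EPS_TAIL))
    return np.minimum(x, np.asarray(upper) - 1e-12 * sd)


def sample_liability(rng, R: np.ndarray, t: int, lp: float,
                     e_row: np.ndarray, category: int) -> float:
    """Draw the liability residual of one record.

    The liability is lp + e_t; it must be > 0 when category is 1 and <= 0
    when 0, so e_t is truncated at -lp on the matching side.
    """
    Rinv = np.linalg.inv(R)
    m, sd = conditional_residual(Rinv, t, e_row)
    if category == 1:
        return float(truncated_normal(rng, np.array([m]), sd, lower=-lp)[0])
    return float(truncated_normal(rng, np.array([m]), sd, upper=-lp)[0])


def impute_missing_continuous(rng, R: np.ndarray, e_row: np.ndarray,
                              missing: np.ndarray) -> np.ndarray:
    """Augment the missing residual cells of one record, one cell at a time
    conditionally on all current cells (no-op on complete records)."""
    e_row = e_row.copy()
    Rinv = np.linalg.inv(R)
    for t in np.flatnonzero(missing):
        m, sd = conditional_residual(Rinv, t, e_row)
        e_row[t] = m + sd * rng.standard_normal()
    return e_row


# ---------------------------------------------------------------------------
# variance-component conditionals

def sample_G(a: np.ndarray, ainv: sp.spmatrix, nu_g: float,
             s0_g: np.ndarray | None, rng) -> np.ndarray:
    """Inverted-Wishart draw of the additive covariance G given the animal
    effects: scale a' A^-1 a + S0, degrees of freedom n_animals + nu."""
    n, T = a.shape
    Sa = a.T @ (ainv @ a)
    if s0_g is not None:
        Sa = Sa + s0_g
    df = n + nu_g
    if df < T:
        raise NumericalError("G conditional degrees of freedom below dimension")
    try:
        G = invwishart.rvs(df=df, scale=Sa, random_state=rng)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"non-PD scale for G draw: {exc}") from exc
    G = np.atleast_2d(G)
    return 0.5 * (G + G.T)


def sample_R(Se: np.ndarray, n: int, traits, nu_r: float,
             s0_r: np.ndarray | None, R_prev: np.ndarray, rng,
             zero_resid_cov_binary: bool = False) -> np.ndarray:
    """Draw R from complete-data residual cross-products Se, keeping the
    binary trait's variance pinned to exactly 1.

    Continuous block: marginal inverted Wishart.  Liability covariances:
    normal conditional for the regression of the liability residual on the
    continuous residuals (conditional variance taken from the previous
    cycle's R), then covariances rebuilt with the pinned unit variance;
    draws implying a non-positive conditional variance are shrunk toward
    the least-squares coefficients.
    """
    T = Se.shape[0]
    kinds = [ts.kind for ts in traits]
    qs = [t for t, k in enumerate(kinds) if k == "binary"]
    if not qs:
        scale = Se + (s0_r if s0_r is not None else 0.0)
        R = np.atleast_2d(invwishart.rvs(df=n + nu_r, scale=scale, random_state=rng))
        return 0.5 * (R + R.T)
    (q,) = qs
    if T == 1:
        return np.ones((1, 1))
    c = [t for t in range(T) if t != q]
    scale11 = Se[np.ix_(c, c)] + (s0_r[np.ix_(c, c)] if s0_r is not None else 0.0)
    R11 = np.atleast_2d(
        invwishart.rvs(df=n + nu_r, scale=scale11, random_state=rng)
    )
    R11 = 0.5 * (R11 + R11.T)
    if zero_resid_cov_binary:
        b = np.zeros(T - 1)
    else:
        XtX = Se[np.ix_(c, c)]
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular residual cross-products: {exc}") from exc
        bhat = XtX_inv @ Se[c, q]
        # conditional variance of the liability residual, anchored on the
        # regression SSE of the augmented residuals (not on the previous
        # cycle's value, which would let the scale random-walk)
        sse = float(Se[q, q] - bhat @ Se[c, q])
        if sse <= 0:
            raise NumericalError("liability residual SSE not positive")
        v = sse / rng.chisquare(max(n - (T - 1), 1))
        cov_b = v * XtX_inv
        b = bhat + np.linalg.cholesky(cov_b) @ rng.standard_normal(T - 1)
        for _ in range(100):
            if 1.0 - b @ R11 @ b > 1e-8:
                break
            b = bhat + 0.7 * (b - bhat)
        else:
            b = np.zeros(T - 1)
    R = np.empty((T, T))
    R[np.ix_(c, c)] = R11
    R[c, q] = R[q, c] = R11 @ b
    R[q, q] = 1.0
    return R


# ---------------------------------------------------------------------------
# vectorised sweeps

def _augmentation_sweep(rng, e, lp_bin, mats: ModelMatrices, Rinv):
    """Liability draws and missing-cell imputations, one trait column at a
    time conditionally on the current state of the other columns."""
    T = mats.n_traits
    for t in range(T):
        prec = Rinv[t, t]
        sd = 1.0 / np.sqrt(prec)
        tot = e @ Rinv[:, t]
        m = e[:, t] - tot / prec
        if mats.traits[t].kind == "binary":
            ones = mats.ybin == 1
            zeros = mats.ybin == 0
            miss = mats.ybin == -1
            if ones.any():
                e[ones, t] = truncated_normal(
                    rng, m[ones], sd, lower=-lp_bin[ones]
                )
            if zeros.any():
                e[zeros, t] = truncated_normal(
                    rng, m[zeros], sd, upper=-lp_bin[zeros]
                )
            if miss.any():
                e[miss, t] = m[miss] + sd * rng.standard_normal(int(miss.sum()))
        else:
            miss = ~mats.obs[:, t]
            if miss.any():
                e[miss, t] = m[miss] + sd * rng.standard_normal(int(miss.sum()))


def sample_location(rng, e, beta_cg, beta_aff, mats: ModelMatrices, Rinv,
                    cg_counts, sxx, beta_prior_var_binary=1.0):
    """Gibbs update of all fixed effects, in place.

    ``beta_cg`` is a list of per-trait level-effect vectors (traits may use
    different CG codings).  Contemporary-group levels within one trait are
    conditionally independent (disjoint record sets), so the whole level
    vector is drawn at once; the AFF slope follows as a scalar site.

    Continuous-trait coefficients carry flat priors.  Liability-scale
    coefficients carry a proper diffuse N(0, beta_prior_var_binary) prior:
    because the binary likelihood depends on location effects only through
    effect / sqrt(1 + sigma_a^2), jointly rescaling all flat-prior
    liability location effects and the genetic variance leaves the
    likelihood unchanged, and the flat prior's infinite mass along that
    ridge makes the posterior improper (it grows with the number of
    contemporary groups).  A diffuse proper prior on the liability scale —
    where real herd-year-season effects are well inside +/-2 — removes the
    ridge with negligible shrinkage of identified effects; None restores
    the flat convention for degenerate single-group models.
    """
    for t in range(mats.n_traits):
        is_binary = mats.traits[t].kind == "binary"
        prior_prec = (
            1.0 / beta_prior_var_binary
            if (is_binary and beta_prior_var_binary is not None) else 0.0
        )
        idx = mats.cg_idx[t]
        counts = cg_counts[t]
        ncg = len(counts)
        u = e @ Rinv[:, t]
        rhs = np.bincount(idx, weights=u, minlength=ncg)
        prec = counts * Rinv[t, t] + prior_prec
        rhs = rhs + counts * Rinv[t, t] * beta_cg[t]
        new = rhs / prec + rng.standard_normal(ncg) / np.sqrt(prec)
        delta = new - beta_cg[t]
        beta_cg[t] = new
        e[:, t] -= delta[idx]
        if mats.traits[t].use_aff:
            u = e @ Rinv[:, t]
            p = sxx * Rinv[t, t] + prior_prec
            r = mats.aff @ u + sxx * Rinv[t, t] * beta_aff[t]
            new_b = r / p + rng.standard_normal() / np.sqrt(p)
            e[:, t] -= (new_b - beta_aff[t]) * mats.aff
            beta_aff[t] = new_b


def animal_full_conditional(k: int, a: np.ndarray, e_sum: np.ndarray,
                            cnt: int, akk: float, neigh: np.ndarray,
                            Rinv: np.ndarray, Ginv: np.ndarray):
    """Mean and covariance of one animal's full conditional (for tests and
    diagnostics; the chain uses the compiled sweep).

    ``e_sum`` is the sum of the animal's record residuals with its own
    effect added back; ``neigh`` is sum_j!=k A^kj a_j.
    """
    P = cnt * Rinv + akk * Ginv
    rhs = Rinv @ e_sum - Ginv @ neigh
    cov = np.linalg.inv(P)
    return cov @ rhs, cov


# ---------------------------------------------------------------------------
# sample store

@dataclass
class SampleStore:
    """Thinned post-burn-in draws of (G, R) plus chain metadata."""

    trait_names: list[str]
    G: np.ndarray                # (S, T, T)
    R: np.ndarray                # (S, T, T)
    cycles: np.ndarray           # (S,)
    config: dict
    seed: int
    location: np.ndarray | None = None   # (S, T, ncg) optional
    aff_slopes: np.ndarray | None = None  # (S, T) optional

    @property
    def n_samples(self) -> int:
        return self.G.shape[0]

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def config_hash(self) -> str:
        payload = json.dumps(
            {"config": self.config, "seed": self.seed,
             "traits": self.trait_names},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        """Plain delimited text: header comments with the config hash and
        metadata, then one row per stored sample holding the cycle index and
        the upper triangles of G and R (the pinned element included for
        completeness — it is identically 1)."""
        T = self.n_traits
        iu = np.triu_indices(T)
        cols = ["cycle"]
        cols += [f"G_{self.trait_names[i]}_{self.trait_names[j]}"
                 for i, j in zip(*iu)]
        cols += [f"R_{self.trait_names[i]}_{self.trait_names[j]}"
                 for i, j in zip(*iu)]
        data = np.column_stack(
            [self.cycles] + [self.G[:, i, j] for i, j in zip(*iu)]
            + [self.R[:, i, j] for i, j in zip(*iu)]
        )
        meta = {"traits": self.trait_names, "seed": self.seed,
                "config": self.config, "hash": self.config_hash()}
        with open(path, "w") as fh:
            fh.write("# ltam sample store\n")
            fh.write(f"# meta: {json.dumps(meta, default=str)}\n")
            pd.DataFrame(data, columns=cols).to_csv(fh, index=False)

    @classmethod
    def load(cls, path) -> "SampleStore":
        meta = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("# meta:"):
                    meta = json.loads(line[len("# meta:"):])
                if not line.startswith("#"):
                    break
        if meta is None:
            raise ValidationError(f"{path} is not a sample store (no meta header)")
        df = pd.read_csv(path, comment="#")
        names = meta["traits"]
        T = len(names)
        S = len(df)
        iu = np.triu_indices(T)
        G = np.zeros((S, T, T))
        R = np.zeros((S, T, T))
        for i, j in zip(*iu):
            G[:, i, j] = G[:, j, i] = df[f"G_{names[i]}_{names[j]}"]
            R[:, i, j] = R[:, j, i] = df[f"R_{names[i]}_{names[j]}"]
        return cls(trait_names=names, G=G, R=R,
                   cycles=df["cycle"].to_numpy(dtype=np.int64),
                   config=meta.get("config", {}), seed=meta.get("seed", 0))


# ---------------------------------------------------------------------------
# the chain

def _check_pd(M: np.ndarray, what: str) -> None:
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"{what} lost positive definiteness") from exc


def _empirical_trait_correlation(mats: ModelMatrices) -> np.ndarray:
    """Pairwise-complete correlation matrix of the trait columns (binary
    columns enter as 0/1), shrunk toward the identity until positive
    definite."""
    T = mats.n_traits
    C = np.eye(T)
    for i in range(T):
        for j in range(i + 1, T):
            both = mats.obs[:, i] & mats.obs[:, j]
            if both.sum() > 2:
                r = np.corrcoef(mats.y[both, i], mats.y[both, j])[0, 1]
                if np.isfinite(r):
                    C[i, j] = C[j, i] = np.clip(r, -0.95, 0.95)
    for _ in range(20):
        if np.linalg.eigvalsh(C).min() > 1e-6:
            break
        C = 0.9 * C + 0.1 * np.eye(T)
    return C


def _initial_state(rng, mats: ModelMatrices, has_ped: bool,
                   init_corr_g: float | None = None,
                   init_empirical_corr: bool = True):
    """Deterministic-given-rng starting values.

    Location effects start at trait means per CG level, liabilities are
    drawn consistent with their category, and (G, R) start from a
    moments-based split of the empirical phenotypic covariance: both take
    the observed trait correlation structure, with a 25/75 variance split
    (the liability residual variance starts pinned at 1).  Starting the
    covariance structure near the data's avoids the long transient in
    which covariance must flow between R and G through the slowly mixing
    animal effects; a chain started at diagonal (G, R) passes through a
    near-singular-G phase that can take tens of thousands of cycles to
    leave.  ``init_corr_g`` overrides the genetic starting correlation
    with a constant (None uses the empirical structure).
    """
    T = mats.n_traits
    nrec = mats.n_records
    vary = np.ones(T)
    beta_cg = [np.zeros(len(mats.cg_labels[t])) for t in range(T)]
    for t, ts in enumerate(mats.traits):
        if ts.kind == "binary":
            continue
        col = mats.y[:, t]
        o = mats.obs[:, t]
        vary[t] = max(float(np.nanvar(col)), 1e-6) if o.any() else 1.0
        beta_cg[t][:] = np.nanmean(col) if o.any() else 0.0
    q = mats.binary_index
    sd_g = np.sqrt(0.25 * vary)
    sd_r = np.sqrt(0.75 * vary)
    if q is not None:
        sd_g[q] = 0.5
        sd_r[q] = 1.0
    C = (_empirical_trait_correlation(mats) if init_empirical_corr
         else np.eye(T))
    if init_corr_g is not None:
        C_g = np.full((T, T), float(init_corr_g))
        np.fill_diagonal(C_g, 1.0)
    else:
        C_g = C
    G = np.outer(sd_g, sd_g) * C_g
    R = np.outer(sd_r, sd_r) * C
    if q is not None:
        R[q, q] = 1.0
    e = np.zeros((nrec, T))
    lp = np.column_stack([beta_cg[t][mats.cg_idx[t]] for t in range(T)])
    a = np.zeros((mats.n_animals, T))
    if has_ped:
        a = rng.standard_normal((mats.n_animals, T)) @ np.linalg.cholesky(G).T
        lp = lp + a[mats.rec_animal]
    for t in range(T):
        o = mats.obs[:, t]
        e[o, t] = mats.y[o, t] - lp[o, t]
        e[~o, t] = rng.standard_normal(int((~o).sum())) * np.sqrt(R[t, t])
    if q is not None:
        sd = np.sqrt(R[q, q])
        ones = mats.ybin == 1
        zeros = mats.ybin == 0
        if ones.any():
            e[ones, q] = truncated_normal(rng, np.zeros(int(ones.sum())), sd,
                                          lower=-lp[ones, q])
        if zeros.any():
            e[zeros, q] = truncated_normal(rng, np.zeros(int(zeros.sum())), sd,
                                           upper=-lp[zeros, q])
    return beta_cg, np.zeros(T), a, e, G, R


def run_chain(
    mats: ModelMatrices,
    ainv: sp.spmatrix | None,
    config: ChainConfig,
    verbose: bool = False,
) -> SampleStore:
    """Run the Gibbs chain and return the thinned post-burn-in draws.

    Fully reproducible: all randomness derives from ``config.seed`` through
    a single numpy Generator (the compiled animal sweep consumes pre-drawn
    normals).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    T = mats.n_traits
    nrec = mats.n_records
    has_ped = mats.rec_animal is not None and mats.n_animals > 0
    q = mats.binary_index

    if has_ped:
        ainv = sp.csr_matrix(ainv)
        if ainv.shape != (mats.n_animals, mats.n_animals):
            raise ValidationError("A inverse order does not match pedigree size")
        # records per animal, CSR-style
        order = np.argsort(mats.rec_animal, kind="stable")
        rec_sorted = order.astype(np.int64)
        rp = np.zeros(mats.n_animals + 1, dtype=np.int64)
        np.add.at(rp[1:], mats.rec_animal, 1)
        rp = np.cumsum(rp).astype(np.int64)
        ai_ptr = ainv.indptr.astype(np.int64)
        ai_idx = ainv.indices.astype(np.int64)
        ai_val = ainv.data.astype(np.float64)

    cg_counts = []
    for t in range(T):
        counts = np.bincount(
            mats.cg_idx[t], minlength=len(mats.cg_labels[t])
        ).astype(float)
        if np.any(counts == 0):
            raise ValidationError("contemporary-group level without records")
        cg_counts.append(counts)
    sxx = float(mats.aff @ mats.aff)
    if any(ts.use_aff for ts in mats.traits) and sxx <= 0:
        raise ValidationError("AFF covariate has no variation")

    # prior resolution: None means the minimally informative default
    # (df = dimension + 1, small diagonal scale); an explicit 0 is flat
    nu_g = T + 1.0 if config.nu_g is None else float(config.nu_g)
    s0_g = config.s0_g
    if s0_g is None and config.nu_g is None:
        s0_g = 0.01 * np.eye(T)
    n_free_r = T - 1 if mats.binary_index is not None and T > 1 else T
    nu_r = n_free_r + 1.0 if config.nu_r is None else float(config.nu_r)
    s0_r = config.s0_r
    if s0_r is None and config.nu_r is None:
        s0_r = 0.01 * np.eye(T)

    beta_cg, beta_aff, a, e, G, R = _initial_state(
        rng, mats, has_ped, init_corr_g=config.init_corr_g,
        init_empirical_corr=config.init_empirical_corr)
    Rinv = np.linalg.inv(R)
    Ginv = np.linalg.inv(G) if has_ped else None
    if not has_ped:
        G = np.zeros((T, T))

    if has_ped and config.blup_start:
        # BLUP start: solve the animal-effect mixed-model equations once at
        # the starting covariances.  This gives the a-field the data's
        # cross-trait structure from cycle one; started from random values,
        # the chain must instead discover that structure through the slowly
        # mixing single-site sweep, during which the genetic covariance can
        # overshoot to a near-singular G it then takes very long to leave.
        w = e + a[mats.rec_animal]
        sums = np.zeros((mats.n_animals, T))
        np.add.at(sums, mats.rec_animal, w)
        rhs = sums @ Rinv
        cnt = np.diff(rp).astype(float)
        P = (sp.kron(sp.diags(cnt), sp.csr_matrix(Rinv), format="csr")
             + sp.kron(ainv, sp.csr_matrix(Ginv), format="csr"))
        a_blup = sp.linalg.spsolve(P.tocsc(), rhs.reshape(-1))
        a_blup = a_blup.reshape(mats.n_animals, T)
        e -= (a_blup - a)[mats.rec_animal]
        a = a_blup

    S = config.n_stored
    store_G = np.empty((S, T, T))
    store_R = np.empty((S, T, T))
    store_cycles = np.empty(S, dtype=np.int64)
    max_ncg = max(len(lab) for lab in mats.cg_labels)
    store_loc = (np.full((S, T, max_ncg), np.nan)
                 if config.store_location else None)
    store_aff = np.empty((S, T)) if config.store_location else None
    s_out = 0

    warmup = config.effective_warmup
    for cycle in range(1, config.n_cycles + 1):
        lp_bin = None
        if q is not None:
            lp_bin = beta_cg[q][mats.cg_idx[q]] + beta_aff[q] * mats.aff
            if has_ped:
                lp_bin = lp_bin + a[mats.rec_animal, q]
        _augmentation_sweep(rng, e, lp_bin, mats, Rinv)
        sample_location(rng, e, beta_cg, beta_aff, mats, Rinv, cg_counts,
                        sxx, beta_prior_var_binary=config.beta_prior_var_binary)
        if has_ped:
            z = rng.standard_normal((mats.n_animals, T))
            try:
                animal_sweep(e, a, Rinv, Ginv, ai_ptr, ai_idx, ai_val,
                             rp, rec_sorted, z)
            except ValueError as exc:
                raise NumericalError(
                    f"cycle {cycle}: {exc}; G={G.tolist()}, R={R.tolist()}"
                ) from exc
        # during the warm-up the location/augmentation state equilibrates
        # under fixed, well-conditioned (G, R); releasing the variance
        # updates afterwards keeps the chain away from the near-singular-G
        # trap a cold start can fall into (warm-up lies inside burn-in and
        # does not change the stationary distribution)
        if cycle > warmup:
            if has_ped:
                G = sample_G(a, ainv, nu_g, s0_g, rng)
                Ginv = np.linalg.inv(G)
            Se = e.T @ e
            R = sample_R(Se, nrec, mats.traits, nu_r, s0_r, R, rng,
                         zero_resid_cov_binary=config.zero_resid_cov_binary)
            Rinv = np.linalg.inv(R)

        if config.validate_every and cycle % config.validate_every == 0:
            _check_pd(R, f"R at cycle {cycle}")
            if has_ped:
                _check_pd(G, f"G at cycle {cycle}")
            if q is not None:
                assert abs(R[q, q] - 1.0) == 0.0
                lp_now = beta_cg[q][mats.cg_idx[q]] + beta_aff[q] * mats.aff
                if has_ped:
                    lp_now = lp_now + a[mats.rec_animal, q]
                lia = lp_now + e[:, q]
                ok1 = np.all(lia[mats.ybin == 1] > 0)
                ok0 = np.all(lia[mats.ybin == 0] <= 0)
                if not (ok1 and ok0):
                    raise NumericalError(
                        f"liability/category inconsistency at cycle {cycle}"
                    )

        if cycle > config.burn_in and (cycle - config.burn_in) % config.thin == 0:
            store_G[s_out] = G
            store_R[s_out] = R
            store_cycles[s_out] = cycle
            if config.store_location:
                for t in range(T):
                    store_loc[s_out, t, :len(beta_cg[t])] = beta_cg[t]
                store_aff[s_out] = beta_aff
            s_out += 1

        if verbose and cycle % 1000 == 0:
            if s_out:
                h2 = np.diag(store_G[:s_out].mean(axis=0)) / (
                    np.diag(store_G[:s_out].mean(axis=0))
                    + np.diag(store_R[:s_out].mean(axis=0))
                )
                logger.info("cycle %d: running-mean h2 = %s",
                            cycle, np.round(h2, 3))
            else:
                logger.info("cycle %d (burn-in)", cycle)

    cfg_dict = {k: v for k, v in asdict(config).items()
                if k not in ("s0_g", "s0_r")}
    return SampleStore(
        trait_names=[ts.name for ts in mats.traits],
        G=store_G, R=store_R, cycles=store_cycles,
        config=cfg_dict, seed=config.seed,
        location=store_loc, aff_slopes=store_aff,
    )


# ---------------------------------------------------------------------------
# estimator facade

class ThresholdAnimalModel(BaseEstimator):
    """Four-trait linear-threshold animal model fitted by Gibbs sampling.

    Parameters mirror :class:`ChainConfig`; ``traits`` defaults to
    (NBA1, NBA2, NBA3 continuous, STAY14 binary).  After :meth:`fit` the
    thinned posterior draws are in ``store_`` and posterior means of the
    covariance matrices and derived genetic parameters in ``G_``, ``R_``,
    ``h2_`` and ``summary_``.

    Examples
    --------
    >>> from ltam import HerdSimulator, ThresholdAnimalModel
    >>> herd = HerdSimulator(n_founder_dams=50, n_founder_sires=10,
    ...                      daughters_per_dam=2).simulate(seed=1)
    >>> table, _ = herd.analysis_table()
    >>> m = ThresholdAnimalModel(n_cycles=500, burn_in=100, thin=10, seed=1)
    >>> m.fit(table, pedigree=herd.pedigree_records)   # doctest: +ELLIPSIS
    ThresholdAnimalModel(...)
    """

    def __init__(self, traits=DEFAULT_TRAITS, n_cycles=250_000,
                 burn_in=50_000, thin=50, seed=0, nu_g=None, s0_g=None,
                 nu_r=None, s0_r=None, zero_resid_cov_binary=False,
                 beta_prior_var_binary=1.0, fixed_var_warmup=500,
                 use_inbreeding=True, store_location=False,
                 merge_extreme_binary_groups=True,
                 validate_every=0, verbose=False):
        self.traits = traits
        self.n_cycles = n_cycles
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.nu_g = nu_g
        self.s0_g = s0_g
        self.nu_r = nu_r
        self.s0_r = s0_r
        self.zero_resid_cov_binary = zero_resid_cov_binary
        self.beta_prior_var_binary = beta_prior_var_binary
        self.fixed_var_warmup = fixed_var_warmup
        self.use_inbreeding = use_inbreeding
        self.store_location = store_location
        self.merge_extreme_binary_groups = merge_extreme_binary_groups
        self.validate_every = validate_every
        self.verbose = verbose

    def _chain_config(self) -> ChainConfig:
        return ChainConfig(
            n_cycles=self.n_cycles, burn_in=self.burn_in, thin=self.thin,
            seed=self.seed, nu_g=self.nu_g, s0_g=self.s0_g, nu_r=self.nu_r,
            s0_r=self.s0_r,
            zero_resid_cov_binary=self.zero_resid_cov_binary,
            beta_prior_var_binary=self.beta_prior_var_binary,
            fixed_var_warmup=self.fixed_var_warmup,
            store_location=self.store_location,
            validate_every=self.validate_every,
        )

    def fit(self, records: pd.DataFrame, pedigree=None, y=None):
        """Fit the model on an analysis table.

        ``pedigree`` may be a list of :class:`PedigreeRecord`, an already
        renumbered pedigree, or None (no genetic effect; degenerate models
        used for calibration checks).  ``y`` is ignored (sklearn API).
        """
        traits = tuple(self.traits)
        if pedigree is None:
            ped = None
            ainv = None
        else:
            if isinstance(pedigree, RenumberedPedigree):
                ped = pedigree
            else:
                ped = renumber(list(pedigree))
            F = compute_inbreeding(ped)
            ainv = build_a_inverse(ped, F, use_inbreeding=self.use_inbreeding)
            self.inbreeding_ = F
        mats = build_matrices(
            records, ped, traits,
            merge_extreme_binary_groups=self.merge_extreme_binary_groups,
        )
        self.matrices_ = mats
        self.pedigree_ = ped
        self.store_ = run_chain(mats, ainv, self._chain_config(),
                                verbose=self.verbose)
        self.G_ = self.store_.G.mean(axis=0)
        self.R_ = self.store_.R.mean(axis=0)
        from .posterior_summary import derive_per_sample, summarize
        self.derived_ = derive_per_sample(self.store_)
        self.summary_ = summarize(self.derived_)
        h2_names = [f"h2_{ts.name}" for ts in traits]
        self.h2_ = self.summary_.loc[h2_names, "mean"].to_numpy()
        self.n_stored_ = self.store_.n_samples
        return self
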