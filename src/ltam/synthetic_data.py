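"""Synthetic pedigreed sow herds with the structure the model assumes.

The generator emulates a multi-herd purebred sow population: a founder
population of sires and dams, discrete generations of daughters produced by
random sire-dam matings, multivariate additive genetic effects dropped down
the pedigree (gene dropping: parent average plus a Mendelian-sampling
deviation with inbreeding-corrected variance), contemporary-group and AFF
effects on the phenotypes, Gaussian litter-size records, a liability-
threshold stayability trait, and culling-driven sequential missingness in
which a sow removed before her fourth farrowing loses all later litter
records.  By default culling is liability-linked (the lowest-liability
culled sows leave earliest), which is exactly the informative-missingness
structure a joint multi-trait analysis is meant to handle; a random-culling
mode isolates the samplers from selection effects for unit tests.

Default scale is 3,000 recorded sows from 150 sires and 1,000 dams — large
enough for parameter recovery, small enough for minutes-scale chains.
Default trait values follow the population the generator emulates: AFF
367 +/- 26 d within [280, 460], litter-size means rising 9.4 -> 10.6 across
parities, a stayability proportion near 0.76 (liability intercept 0.7),
and births spread over 2004-2014 with data collection ending 2015-12-31 so
a realistic minority of sows is right-censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
import json

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .data_prep import make_cg, read_sow_records, edit_records
from .pedigree import PedigreeRecord, RenumberedPedigree, renumber, compute_inbreeding

TRAITS = ("nba1", "nba2", "nba3", "stay14")


def _default_G() -> np.ndarray:
    """Additive covariance: h2 = 0.30 for the litter traits (sigma_p^2 =
    6.5, on the scale of field litter-size variances), h2 = 0.25 on the
    liability scale (sigma_a^2 = 1/3 against the unit residual), genetic
    correlation 0.6 between every pair."""
    sa = np.sqrt(np.array([1.95, 1.95, 1.95, 1.0 / 3.0]))
    G = 0.6 * np.outer(sa, sa)
    np.fill_diagonal(G, sa ** 2)
    return G


def _default_R() -> np.ndarray:
    """Residual covariance: litter residual variance 4.55 (so sigma_p^2 =
    6.5), liability residual pinned at 1, residual correlation 0.1."""
    se = np.sqrt(np.array([4.55, 4.55, 4.55, 1.0]))
    R = 0.1 * np.outer(se, se)
    np.fill_diagonal(R, se ** 2)
    return R


@dataclass
class SimConfig:
    """True parameters and structure of the simulated herd."""

    n_founder_sires: int = 150
    n_founder_dams: int = 1000
    daughters_per_dam: int = 3
    n_generations: int = 1
    true_G: np.ndarray = field(default_factory=_default_G)
    true_R: np.ndarray = field(default_factory=_default_R)
    intercepts: tuple = (9.4, 10.0, 10.6, 0.7)
    n_herds: int = 3
    cg_effect_sd: tuple = (0.3, 0.3, 0.3, 0.2)
    aff_mean: float = 367.0
    aff_sd: float = 26.0
    aff_range: tuple = (280.0, 460.0)
    aff_slope: tuple = (-0.005, -0.005, -0.005, -0.003)
    farrow_interval_mean: float = 155.0
    farrow_interval_sd: float = 8.0
    birth_year_range: tuple = (2010, 2013)
    data_end: date = date(2015, 12, 31)
    culling: str = "liability"        # or "random"
    removal_parity_probs: tuple = (1 / 3, 1 / 3, 1 / 3)
    round_litter: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name, M in (("true_G", self.true_G), ("true_R", self.true_R)):
            M = np.asarray(M, dtype=float)
            if M.shape != (4, 4) or not np.allclose(M, M.T):
                raise ValidationError(f"{name} must be symmetric 4x4")
            if not np.all(np.linalg.eigvalsh(M) >= -1e-10):
                raise ValidationError(f"{name} is not positive semidefinite")
        if abs(float(np.asarray(self.true_R)[3, 3]) - 1.0) > 1e-12:
            raise ValidationError("true_R[4,4] (liability residual) must be 1")
        p = np.asarray(self.removal_parity_probs, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError("removal_parity_probs must be 3 probabilities summing to 1")
        if self.culling not in ("liability", "random"):
            raise ValidationError(f"unknown culling mode {self.culling!r}")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["true_G"] = np.asarray(self.true_G).tolist()
        d["true_R"] = np.asarray(self.true_R).tolist()
        d["data_end"] = self.data_end.isoformat()
        return d


@dataclass
class SimulatedHerd:
    """A simulated herd: pedigree, sow records, and the generating truth."""

    config: SimConfig
    pedigree_records: list[PedigreeRecord]
    pedigree: RenumberedPedigree
    sow_ids: list[str]
    breeding_values: np.ndarray      # (n_animals, 4), pedigree code order
    sows: pd.DataFrame               # one row per recorded sow (truth + records)
    events: pd.DataFrame             # long farrowing-event table

    def analysis_table(self):
        """Run the herd through the editing pipeline (round trip)."""
        import io

        buf = io.StringIO()
        self._write_events(buf)
        buf.seek(0)
        records = read_sow_records(buf)
        return edit_records(records, data_end_date=self.config.data_end)

    def expected_analysis(self) -> pd.DataFrame:
        """The analysis table the generator itself implies, for round-trip
        checks against the editing pipeline."""
        cols = ["sow", "cg", "aff", "nba1_obs", "nba2_obs", "nba3_obs",
                "stay14_obs"]
        df = self.sows.loc[self.sows["has_record"], cols].rename(
            columns={f"{t}_obs": t for t in TRAITS}
        ).reset_index(drop=True)
        return df

    def _write_events(self, fh) -> None:
        self.events.to_csv(fh, index=False)

    def to_files(self, outdir) -> dict:
        """Write pedigree.csv, records.csv and the truth sidecar; returns
        the mapping of logical name -> path."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pedigree": outdir / "pedigree.csv",
            "records": outdir / "records.csv",
            "truth_values": outdir / "truth_values.csv",
            "truth_params": outdir / "truth_params.json",
        }
        with open(paths["pedigree"], "w") as fh:
            fh.write("animal,sire,dam\n")
            for rec in self.pedigree_records:
                fh.write(f"{rec.animal},{rec.sire or 0},{rec.dam or 0}\n")
        with open(paths["records"], "w") as fh:
            self._write_events(fh)
        truth = self.sows[["sow", "liability", "stay_true"]].copy()
        bv = self.breeding_values
        codes = [self.pedigree.code_of[s] - 1 for s in self.sows["sow"]]
        for t, nm in enumerate(TRAITS):
            truth[f"bv_{nm}"] = bv[codes, t]
        truth.to_csv(paths["truth_values"], index=False)
        with open(paths["truth_params"], "w") as fh:
            json.dump(self.config.to_jsonable(), fh, indent=1)
        return paths


def simulate_pedigree(config: SimConfig, rng) -> tuple[list[PedigreeRecord], list[str]]:
    """Discrete-generation pedigree: unrelated founders, each dam of a
    generation mated to a random founder sire, ``daughters_per_dam``
    daughters per mating.  Returns the records and the ids of recorded sows
    (all non-founder females)."""
    records = []
    sires = [f"S{i+1}" for i in range(config.n_founder_sires)]
    dams = [f"D{i+1}" for i in range(config.n_founder_dams)]
    for s in sires:
        records.append(PedigreeRecord(s))
    for d in dams:
        records.append(PedigreeRecord(d))
    sows = []
    current_dams = dams
    for g in range(1, config.n_generations + 1):
        next_gen = []
        for j, d in enumerate(current_dams):
            s = sires[rng.integers(len(sires))]
            for k in range(config.daughters_per_dam):
                child = f"G{g}F{j+1}_{k+1}"
                records.append(PedigreeRecord(child, sire=s, dam=d))
                next_gen.append(child)
        sows.extend(next_gen)
        current_dams = next_gen
    return records, sows


def drop_breeding_values(ped: RenumberedPedigree, true_G: np.ndarray, rng,
                         F: np.ndarray | None = None) -> np.ndarray:
    """Gene-drop multivariate breeding values down the pedigree.

    Founders ~ N(0, G); non-founders are the parent average (unknown
    parents contributing 0) plus a Mendelian deviation with variance d_i G,
    d_i = 0.5 - 0.25 (F_s + F_d) and F of an unknown parent taken as -1.
    """
    true_G = np.asarray(true_G, dtype=float)
    T = true_G.shape[0]
    n = ped.n
    a = np.zeros((n, T))
    if not true_G.any():
        return a
    try:
        cholG = np.linalg.cholesky(true_G)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("true_G is not positive definite") from exc
    if F is None:
        F = compute_inbreeding(ped)
    Fpad = np.concatenate(([-1.0], F))
    z = rng.standard_normal((n, T))
    for i in range(1, n + 1):
        s, d = ped.sire[i], ped.dam[i]
        di = 0.5 - 0.25 * (Fpad[s] + Fpad[d])
        mean = np.zeros(T)
        if s > 0:
            mean += 0.5 * a[s - 1]
        if d > 0:
            mean += 0.5 * a[d - 1]
        a[i - 1] = mean + np.sqrt(di) * (cholG @ z[i - 1])
    return a


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Inverse-CDF truncated normal draws on [lo, hi]."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = a + rng.random(size) * (b - a)
    return mean + sd * ndtri(np.clip(u, 1e-12, 1 - 1e-12))


def simulate_records(ped: RenumberedPedigree, sow_ids: list[str],
                     bv: np.ndarray, config: SimConfig, rng) -> pd.DataFrame:
    """Phenotypes and calendar structure for the recorded sows.

    Returns one row per sow with herd, dates, CG label, true (pre-culling)
    litter sizes at parities 1-3, the stayability liability and its
    category.  Phenotype: intercept + CG effect + slope * (AFF - mean) +
    breeding value + residual from true_R; stayability is liability > 0.
    """
    n = len(sow_ids)
    codes = np.array([ped.code_of[s] - 1 for s in sow_ids])
    aff = np.round(
        _truncnorm(rng, config.aff_mean, config.aff_sd,
                   config.aff_range[0], config.aff_range[1], n)
    )
    y0, y1 = config.birth_year_range
    start = pd.Timestamp(date(y0, 1, 1))
    ndays = (pd.Timestamp(date(y1, 12, 31)) - start).days
    birth = start + pd.to_timedelta(rng.integers(0, ndays + 1, size=n), unit="D")
    first_farrow = birth + pd.to_timedelta(aff.astype(int), unit="D")
    herd = np.array([f"H{h+1}" for h in rng.integers(config.n_herds, size=n)])
    cg = np.array([
        make_cg(h, d.date()) for h, d in zip(herd, first_farrow)
    ])
    labels, inv = np.unique(cg, return_inverse=True)
    cg_sd = np.asarray(config.cg_effect_sd, dtype=float)
    cg_eff = rng.standard_normal((len(labels), 4)) * cg_sd
    slopes = np.asarray(config.aff_slope, dtype=float)
    true_R = np.asarray(config.true_R, dtype=float)
    resid = rng.standard_normal((n, 4)) @ np.linalg.cholesky(true_R).T
    lin = (
        np.asarray(config.intercepts, dtype=float)
        + cg_eff[inv]
        + np.outer(aff - config.aff_mean, slopes)
    )
    pheno = lin + bv[codes] + resid
    nba = pheno[:, :3]
    if config.round_litter:
        nba = np.maximum(np.rint(nba), 0.0)
    liability = pheno[:, 3]
    intervals = np.maximum(
        rng.normal(config.farrow_interval_mean, config.farrow_interval_sd,
                   size=(n, 3)), 90.0
    ).astype(int)
    farrow_dates = np.empty((n, 4), dtype="datetime64[ns]")
    farrow_dates[:, 0] = first_farrow.to_numpy()
    for k in range(1, 4):
        farrow_dates[:, k] = farrow_dates[:, k - 1] + intervals[:, k - 1].astype(
            "timedelta64[D]"
        )
    sows = pd.DataFrame({
        "sow": sow_ids, "herd": herd, "birth_date": birth,
        "aff": aff, "cg": cg,
        "nba1_true": nba[:, 0], "nba2_true": nba[:, 1], "nba3_true": nba[:, 2],
        "liability": liability, "stay_true": (liability > 0).astype(int),
    })
    for k in range(4):
        sows[f"farrow{k+1}"] = farrow_dates[:, k]
    return sows


def apply_sequential_missingness(sows: pd.DataFrame, config: SimConfig,
                                 rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impose culling and right censoring; build the farrowing-event table.

    Sows with a negative stayability liability are assigned a removal
    parity in {1,2,3}: liability-linked mode removes the lowest-liability
    culled sows earliest (fractions given by removal_parity_probs); random
    mode assigns parities multinomially.  Litter records after the removal
    parity are deleted and a removal date is set 30 d after the last
    farrowing.  Events after the end of data collection are censored:
    the sow is then still in the herd and her stayability is missing.
    """
    sows = sows.copy()
    n = len(sows)
    culled = sows["stay_true"].to_numpy() == 0
    removal_parity = np.full(n, 0, dtype=int)  # 0 = never removed
    idx = np.flatnonzero(culled)
    probs = np.asarray(config.removal_parity_probs, dtype=float)
    if idx.size:
        if config.culling == "liability":
            order = idx[np.argsort(sows["liability"].to_numpy()[idx])]
            cuts = np.floor(np.cumsum(probs) * idx.size).astype(int)
            removal_parity[order[: cuts[0]]] = 1
            removal_parity[order[cuts[0]:cuts[1]]] = 2
            removal_parity[order[cuts[1]:]] = 3
        else:
            removal_parity[idx] = rng.choice([1, 2, 3], size=idx.size, p=probs)
    sows["removal_parity"] = removal_parity

    data_end = np.datetime64(pd.Timestamp(config.data_end))
    farrow = np.stack(
        [sows[f"farrow{k}"].to_numpy() for k in (1, 2, 3, 4)], axis=1
    )
    nba_true = np.stack(
        [sows[f"nba{k}_true"].to_numpy() for k in (1, 2, 3)], axis=1
    )
    last_parity = np.where(removal_parity == 0, 4, removal_parity)
    # farrowing dates increase with parity, so "seen" is a prefix mask
    seen = (farrow <= data_end) & (
        np.arange(1, 5)[None, :] <= last_parity[:, None]
    )
    seen = np.cumprod(seen, axis=1).astype(bool)
    n_seen = seen.sum(axis=1)
    removed = removal_parity > 0
    rdate = np.full(n, np.datetime64("NaT"), dtype="datetime64[ns]")
    if removed.any():
        rdate[removed] = (
            farrow[np.flatnonzero(removed), removal_parity[removed] - 1]
            + np.timedelta64(30, "D")
        )
    removal_known = removed & (rdate <= data_end)
    rdate[~removal_known] = np.datetime64("NaT")
    stay_obs = np.where(
        n_seen >= 4, 1.0, np.where(removal_known, 0.0, np.nan)
    )
    for k in (1, 2, 3):
        sows[f"nba{k}_obs"] = np.where(seen[:, k - 1], nba_true[:, k - 1], np.nan)
    sows["stay14_obs"] = stay_obs
    sows["removal_date"] = rdate
    sows["has_record"] = n_seen >= 1

    removal_str = np.where(
        removal_known,
        pd.Series(rdate).dt.strftime("%Y-%m-%d").fillna(""), "",
    )
    birth_str = sows["birth_date"].dt.strftime("%Y-%m-%d").to_numpy()
    chunks = []
    for k in (1, 2, 3, 4):
        sel = seen[:, k - 1]
        if not sel.any():
            continue
        chunks.append(pd.DataFrame({
            "sow": sows["sow"].to_numpy()[sel],
            "herd": sows["herd"].to_numpy()[sel],
            "birth_date": birth_str[sel],
            "parity": k,
            "farrow_date": pd.Series(farrow[sel, k - 1]).dt.strftime(
                "%Y-%m-%d").to_numpy(),
            "nba": nba_true[sel, k - 1] if k <= 3 else np.nan,
            "removal_date": removal_str[sel],
        }))
    events = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame(
        columns=["sow", "herd", "birth_date", "parity", "farrow_date",
                 "nba", "removal_date"]
    )
    events = events.sort_values(["sow", "parity"], kind="stable",
                                ignore_index=True)
    return sows, events


class HerdSimulator(BaseEstimator):
    """Configurable herd generator (parameters are the SimConfig fields)."""

    def __init__(self, n_founder_sires=150, n_founder_dams=1000,
                 daughters_per_dam=3, n_generations=1, true_G=None,
                 true_R=None, intercepts=(9.4, 10.0, 10.6, 0.7), n_herds=3,
                 cg_effect_sd=(0.3, 0.3, 0.3, 0.2), aff_mean=367.0,
                 aff_sd=26.0, aff_range=(280.0, 460.0),
                 aff_slope=(-0.005, -0.005, -0.005, -0.003),
                 farrow_interval_mean=155.0, farrow_interval_sd=8.0,
                 birth_year_range=(2010, 2013), data_end=date(2015, 12, 31),
                 culling="liability",
                 removal_parity_probs=(1 / 3, 1 / 3, 1 / 3),
                 round_litter=False, seed=0):
        self.n_founder_sires = n_founder_sires
        self.n_founder_dams = n_founder_dams
        self.daughters_per_dam = daughters_per_dam
        self.n_generations = n_generations
        self.true_G = true_G
        self.true_R = true_R
        self.intercepts = intercepts
        self.n_herds = n_herds
        self.cg_effect_sd = cg_effect_sd
        self.aff_mean = aff_mean
        self.aff_sd = aff_sd
        self.aff_range = aff_range
        self.aff_slope = aff_slope
        self.farrow_interval_mean = farrow_interval_mean
        self.farrow_interval_sd = farrow_interval_sd
        self.birth_year_range = birth_year_range
        self.data_end = data_end
        self.culling = culling
        self.removal_parity_probs = removal_parity_probs
        self.round_litter = round_litter
        self.seed = seed

    def config(self) -> SimConfig:
        params = self.get_params()
        if params["true_G"] is None:
            params["true_G"] = _default_G()
        if params["true_R"] is None:
            params["true_R"] = _default_R()
        cfg = SimConfig(**params)
        cfg.validate()
        return cfg

    def simulate(self, seed: int | None = None) -> SimulatedHerd:
        cfg = self.config()
        if seed is not None:
            cfg.seed = seed
        rng = np.random.default_rng(cfg.seed)
        ped_records, sow_ids = simulate_pedigree(cfg, rng)
        ped = renumber(ped_records)
        bv = drop_breeding_values(ped, cfg.true_G, rng)
        sows = simulate_records(ped, sow_ids, bv, cfg, rng)
        sows, events = apply_sequential_missingness(sows, cfg, rng)
        return SimulatedHerd(
            config=cfg, pedigree_records=ped_records, pedigree=ped,
            sow_ids=sow_ids, breeding_values=bv, sows=sows, events=events,
        )
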