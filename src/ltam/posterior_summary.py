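"""Posterior summaries of the variance-component draws.

Every stored (G, R) draw is first converted into the derived genetic
parameters — per-trait additive, residual and phenotypic variances and
heritability, pairwise genetic and phenotypic correlations — and the
posterior mean and SD are taken over those derived values (mean of the
ratio, never ratio of means).  For the threshold trait the pinned unit
residual variance makes h2 = sigma_a^2 / (sigma_a^2 + 1) exactly.

Two report styles mirror the usual presentation of such analyses: a
variance-component table (sigma_a^2, sigma_e^2, sigma_p^2, h2 per trait,
each "mean (SD)") and a correlation matrix with heritabilities on the
diagonal, genetic correlations above and phenotypic correlations below.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .errors import ValidationError
from .threshold_model import SampleStore


def derive_one(G: np.ndarray, R: np.ndarray, names) -> dict:
    """Derived parameters for a single (G, R) draw."""
    T = len(names)
    out = {}
    sp2 = np.diag(G) + np.diag(R)
    with np.errstate(divide="ignore", invalid="ignore"):
        for t, nm in enumerate(names):
            out[f"sigma_a2_{nm}"] = G[t, t]
            out[f"sigma_e2_{nm}"] = R[t, t]
            out[f"sigma_p2_{nm}"] = sp2[t]
            out[f"h2_{nm}"] = G[t, t] / sp2[t] if sp2[t] > 0 else np.nan
        for i in range(T):
            for j in range(i + 1, T):
                gg = G[i, i] * G[j, j]
                out[f"rg_{names[i]}_{names[j]}"] = (
                    G[i, j] / np.sqrt(gg) if gg > 0 else np.nan
                )
                pp = sp2[i] * sp2[j]
                out[f"rp_{names[i]}_{names[j]}"] = (
                    (G[i, j] + R[i, j]) / np.sqrt(pp) if pp > 0 else np.nan
                )
    return out


def derive_per_sample(store: SampleStore) -> pd.DataFrame:
    """Derived parameters for every stored draw (one row per draw)."""
    if store.n_samples == 0:
        raise ValidationError("empty sample store")
    for s in range(store.n_samples):
        try:
            np.linalg.cholesky(store.R[s])
        except np.linalg.LinAlgError:
            raise ValidationError(f"stored R draw {s} is not positive definite")
    rows = [derive_one(store.G[s], store.R[s], store.trait_names)
            for s in range(store.n_samples)]
    return pd.DataFrame(rows)


def summarize(derived: pd.DataFrame) -> pd.DataFrame:
    """Posterior mean and SD per derived quantity.

    Returns a DataFrame indexed by quantity with columns mean, sd, n.
    """
    if len(derived) < 2:
        raise ValidationError("need at least 2 samples to summarize")
    out = pd.DataFrame({
        "mean": derived.mean(axis=0),
        "sd": derived.std(axis=0, ddof=1),
        "n": len(derived),
    })
    return out


def _cell(summary: pd.DataFrame, key: str) -> str:
    m = summary.loc[key, "mean"]
    s = summary.loc[key, "sd"]
    return f"{m:.2f} ({s:.2f})"


def format_report(summary: pd.DataFrame, style: str = "components",
                  trait_names=("nba1", "nba2", "nba3", "stay14")) -> str:
    """Render a text table from a parameter summary.

    ``components``: one row per trait with sigma_a^2, sigma_e^2,
    sigma_p^2 and h2, each as "mean (SD)".  ``correlation_matrix``: h2 on
    the diagonal (marked with *), genetic correlations above it,
    phenotypic correlations below.  Values are rounded to 2 decimals; the
    dispersion in brackets is the posterior SD.
    """
    names = list(trait_names)
    if style == "components":
        header = f"{'trait':<10}{'sigma_a2':>14}{'sigma_e2':>14}" \
                 f"{'sigma_p2':>14}{'h2':>14}"
        lines = [header]
        for nm in names:
            lines.append(
                f"{nm:<10}"
                f"{_cell(summary, f'sigma_a2_{nm}'):>14}"
                f"{_cell(summary, f'sigma_e2_{nm}'):>14}"
                f"{_cell(summary, f'sigma_p2_{nm}'):>14}"
                f"{_cell(summary, f'h2_{nm}'):>14}"
            )
        return "\n".join(lines)
    if style == "correlation_matrix":
        width = 16
        lines = ["".join([f"{'':<10}"] + [f"{nm:>{width}}" for nm in names])]
        for i, ni in enumerate(names):
            cells = []
            for j, nj in enumerate(names):
                if i == j:
                    cells.append("*" + _cell(summary, f"h2_{ni}"))
                elif i < j:
                    cells.append(_cell(summary, f"rg_{ni}_{nj}"))
                else:
                    cells.append(_cell(summary, f"rp_{nj}_{ni}"))
            lines.append("".join([f"{ni:<10}"] + [f"{c:>{width}}" for c in cells]))
        return "\n".join(lines)
    raise ValidationError(f"unknown report style {style!r}")


_CELL_RE = re.compile(r"\*?(-?\d+\.\d+) \((-?\d+\.\d+)\)")


def parse_report(text: str) -> pd.DataFrame:
    """Parse a formatted report back into rounded (mean, sd) cells.

    Returns a DataFrame with columns row, col, mean, sd where row is the
    trait of the table line and col the column position.  Used to verify
    the report round-trips its rounded values.
    """
    rows = []
    lines = text.splitlines()
    for line in lines[1:]:
        name = line.split()[0]
        for k, m in enumerate(_CELL_RE.finditer(line)):
            rows.append({"row": name, "col": k,
                         "mean": float(m.group(1)), "sd": float(m.group(2))})
    return pd.DataFrame(rows)


def write_summary(summary: pd.DataFrame, path) -> None:
    """Machine-readable full-precision sidecar."""
    summary.to_csv(path, index_label="quantity")


def trace_plot(store: SampleStore, quantity: str, path) -> None:
    """Save a trace plot of one derived quantity across stored cycles."""
    from matplotlib.figure import Figure

    derived = derive_per_sample(store)
    if quantity not in derived.columns:
        raise ValidationError(f"unknown quantity {quantity!r}")
    fig = Figure(figsize=(8, 3))
    ax = fig.add_subplot(111)
    ax.plot(store.cycles, derived[quantity], lw=0.5)
    ax.set_xlabel("cycle")
    ax.set_ylabel(quantity)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
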