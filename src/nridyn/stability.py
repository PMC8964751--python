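"""Mutation-stability scoring from learned interaction graphs.

The learned-edge free-energy score E_z of a variant is the sum of its
learned edge weights over residue pairs whose reference C-alpha distance
falls below a cutoff (12 or 15 Angstrom in the canonical protocol).  The
relative score Delta G_Z = E_z(variant) - E_z(wild type) tracks the change
in structural stability caused by the mutation and is correlated against
experimental unfolding free-energy differences (Delta Delta G, kcal/mol)
with a plain two-sided Pearson test (df = n - 2), no multiple-testing
adjustment.  Absolute free energies are out of scope: only the trend is
meaningful.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from .graph import InteractionMatrix

__all__ = [
    "DistanceReference",
    "StabilityReport",
    "pairwise_energy_score",
    "delta_g_scores",
    "correlate_with_experiment",
    "load_experimental_ddg",
]


@dataclass
class DistanceReference:
    """Pairwise C-alpha distances from one reference structure (never
    per-frame)."""

    coordinates: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("reference coordinates must have shape (N, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite reference coordinates")
        if not self.node_labels:
            self.node_labels = [str(i) for i in range(len(self.coordinates))]

    @property
    def n_nodes(self) -> int:
        return self.coordinates.shape[0]

    def distances(self) -> np.ndarray:
        """Symmetric (N, N) distance matrix, zero diagonal."""
        return squareform(pdist(self.coordinates))

    @classmethod
    def from_trajectory_frame(cls, raw, frame: int = 0) -> "DistanceReference":
        return cls(raw.positions[frame], node_labels=list(raw.node_labels))


@dataclass
class StabilityReport:
    """Per-variant E_z and Delta G_Z plus the correlation statistics."""

    e_z: dict[str, float]
    delta_g_z: dict[str, float]
    threshold: float
    r_squared: float | None = None
    r_squared_unsigned: float | None = None
    p_value: float | None = None
    ci95: tuple[float, float] | None = None
    df: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variant": v, "E_z": self.e_z[v], "dG_Z": self.delta_g_z[v]}
                for v in self.e_z]
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {
            "threshold_angstrom": self.threshold,
            "E_z": self.e_z,
            "delta_G_Z": self.delta_g_z,
            "R2_signed": self.r_squared,
            "R2_unsigned": self.r_squared_unsigned,
            "p_value": self.p_value,
            "ci95": list(self.ci95) if self.ci95 else None,
            "df": self.df,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def pairwise_energy_score(m: InteractionMatrix, ref: DistanceReference,
                          threshold: float, ordered_pairs: bool = True) -> float:
    """E_z: sum of learned-edge weights over pairs with reference C-alpha
    distance <= threshold (Angstrom).

    ``ordered_pairs=False`` sums each unordered pair's mean weight once; the
    factor of two cancels in any correlation.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive (Angstrom)")
    if ref.n_nodes != m.n_nodes:
        raise ValueError(
            f"reference covers {ref.n_nodes} nodes, matrix has {m.n_nodes}"
        )
    within = ref.distances() <= threshold
    np.fill_diagonal(within, False)
    if ordered_pairs:
        return float(m.w[within].sum())
    sym = 0.5 * (m.w + m.w.T)
    return float(sym[np.triu(within)].sum())


def delta_g_scores(variants: dict[str, InteractionMatrix],
                   wt: InteractionMatrix, ref: DistanceReference,
                   threshold: float) -> StabilityReport:
    """Delta G_Z per variant relative to wild type (WT entry exactly 0)."""
    e_wt = pairwise_energy_score(wt, ref, threshold)
    e_z = {"WT": e_wt}
    delta = {"WT": 0.0}
    for name, matrix in variants.items():
        if matrix.n_nodes != wt.n_nodes:
            raise ValueError(f"variant {name!r} has {matrix.n_nodes} nodes, "
                             f"WT has {wt.n_nodes}")
        e_z[name] = pairwise_energy_score(matrix, ref, threshold)
        delta[name] = e_z[name] - e_wt
    return StabilityReport(e_z=e_z, delta_g_z=delta, threshold=threshold)


def correlate_with_experiment(delta_gz, ddg_exp) -> tuple[float, float, tuple[float, float], int]:
    """Pearson correlation of computed scores against experimental
    Delta Delta G.

    Returns (R2, p, CI95, df): R2 carries the sign of r (so anticorrelation
    reports a negative value); p is two-sided with df = n - 2; the 95%
    confidence interval on R2 comes from the Fisher z interval on r.
    """
    x = np.asarray(delta_gz, dtype=float)
    y = np.asarray(ddg_exp, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    df = n - 2
    z = np.arctanh(r)
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    r_lo, r_hi = np.tanh(z - half), np.tanh(z + half)
    signed_sq = lambda v: float(np.sign(v) * v * v)
    ci = tuple(sorted((signed_sq(r_lo), signed_sq(r_hi))))
    return signed_sq(r), float(p), ci, df


def attach_correlation(report: StabilityReport, ddg_table: pd.DataFrame) -> StabilityReport:
    """Fill the report's correlation fields from an experimental table with
    columns ``variant`` and ``ddG_kcal_per_mol`` (WT excluded)."""
    variants = [v for v in report.delta_g_z if v != "WT"]
    merged = ddg_table.set_index("variant").loc[
        [v for v in variants if v in set(ddg_table["variant"])]
    ]
    x = np.array([report.delta_g_z[v] for v in merged.index])
    y = merged["ddG_kcal_per_mol"].to_numpy(dtype=float)
    r2, p, ci, df = correlate_with_experiment(x, y)
    r, _ = stats.pearsonr(x, y)
    report.r_squared = r2
    report.r_squared_unsigned = float(r * r)
    report.p_value = p
    report.ci95 = ci
    report.df = df
    return report


def load_experimental_ddg(path) -> pd.DataFrame:
    """Read a TSV ``variant  ddG_kcal_per_mol``; 'ND' (not determined)
    entries are dropped with a warning."""
    table = pd.read_csv(path, sep="\t", dtype={"variant": str})
    if "ddG_kcal_per_mol" not in table.columns:
        raise ValueError("expected columns: variant, ddG_kcal_per_mol")
    nd = table["ddG_kcal_per_mol"].astype(str).str.upper().isin(["ND", "N.D."])
    if nd.any():
        warnings.warn(
            f"dropping {int(nd.sum())} variants with undetermined ddG: "
            f"{', '.join(table.loc[nd, 'variant'])}",
            stacklevel=2,
        )
        table = table[~nd]
    table = table.copy()
    table["ddG_kcal_per_mol"] = table["ddG_kcal_per_mol"].astype(float)
    return table.reset_index(drop=True)
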