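"""Downstream operations on fitted personalized networks.

A fitted network is a coefficient tensor indexed (target gene, regulator,
target sample).  The operations here condense that tensor the way a
drug-sensitivity analysis consumes it: median aggregation within a sample
group, consensus across several drugs, top-|weight| filtering for display,
a principal-component summary of multi-drug sensitivities, and a per-regulator
"effect change" score (the range of each varying coefficient across target
samples) flagging modulator-specific regulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import NetgicError

__all__ = [
    "PersonalizedNetwork",
    "EdgeTable",
    "aggregate_group_median",
    "consensus_mean",
    "top_fraction_edges",
    "drug_sensitivity_module",
    "regulate_effect_change",
]


@dataclass
class PersonalizedNetwork:
    """Coefficient tensor ``coef[target, regulator, sample]``.

    Diagonal entries (self-edges) are structurally zero and never exported.
    """

    coef: np.ndarray
    gene_ids: list
    target_sample_ids: list
    modulator_values: np.ndarray | None = None
    failures: list = field(default_factory=list)

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.ndim != 3:
            raise NetgicError("coef must be a 3-D tensor (target, regulator, sample)")
        q1, q2, T = self.coef.shape
        if q1 != q2 or q1 != len(self.gene_ids):
            raise NetgicError("coef gene axes must match gene_ids")
        if T != len(self.target_sample_ids):
            raise NetgicError("coef sample axis must match target_sample_ids")
        if not np.all(np.isfinite(self.coef)):
            raise NetgicError("coefficients must be finite")

    @property
    def n_genes(self):
        return len(self.gene_ids)

    @property
    def n_target_samples(self):
        return len(self.target_sample_ids)

    def sample_positions(self, sample_ids):
        pos = []
        for s in sample_ids:
            try:
                pos.append(self.target_sample_ids.index(str(s)))
            except ValueError:
                raise NetgicError(f"unknown target sample {s!r}") from None
        return np.asarray(pos, dtype=int)

    def edge_table(self, sample) -> "EdgeTable":
        """Edge list (regulator, target, weight) for one target sample."""
        t = self.sample_positions([sample])[0]
        return _tensor_slice_to_table(self.coef[:, :, t], self.gene_ids)


@dataclass
class EdgeTable:
    """Directed weighted edge list with unique (regulator, target) rows."""

    df: pd.DataFrame

    def __post_init__(self):
        need = {"regulator", "target", "weight"}
        if not need.issubset(self.df.columns):
            raise NetgicError(f"edge table needs columns {sorted(need)}")
        df = self.df.reset_index(drop=True)
        if (df["regulator"] == df["target"]).any():
            raise NetgicError("self-edges are not allowed")
        if df.duplicated(["regulator", "target"]).any():
            raise NetgicError("(regulator, target) pairs must be unique")
        if not np.all(np.isfinite(df["weight"].to_numpy(dtype=float))):
            raise NetgicError("edge weights must be finite")
        self.df = df

    def __len__(self):
        return len(self.df)

    def nonzero(self) -> "EdgeTable":
        return EdgeTable(self.df[self.df["weight"] != 0.0].reset_index(drop=True))

    def gene_universe(self):
        return set(self.df["regulator"]) | set(self.df["target"])


def _tensor_slice_to_table(mat, gene_ids) -> EdgeTable:
    """All off-diagonal entries of a (target x regulator) matrix as edges."""
    q = len(gene_ids)
    tgt, reg = np.nonzero(~np.eye(q, dtype=bool))
    df = pd.DataFrame({
        "regulator": [gene_ids[j] for j in reg],
        "target": [gene_ids[i] for i in tgt],
        "weight": mat[tgt, reg],
    })
    return EdgeTable(df)


def aggregate_group_median(net: PersonalizedNetwork, group) -> EdgeTable:
    """Median edge weight over a group of target samples, per edge."""
    group = list(group)
    if not group:
        raise NetgicError("group must be nonempty")
    pos = net.sample_positions(group)
    med = np.median(net.coef[:, :, pos], axis=2)
    return _tensor_slice_to_table(med, net.gene_ids)


def consensus_mean(tables, *, strict_universe=True) -> EdgeTable:
    """Mean weight over tables, restricted to edges nonzero in every table.

    Used to build e.g. a drug-resistant-specific consensus network from the
    per-drug median networks.  With ``strict_universe`` the tables must all
    mention the same genes; disable it for edge lists already filtered to
    their nonzero support.
    """
    tables = list(tables)
    if not tables:
        raise NetgicError("need at least one edge table")
    if strict_universe:
        universe = tables[0].gene_universe()
        for t in tables[1:]:
            if t.gene_universe() != universe:
                raise NetgicError("edge tables have inconsistent gene universes")
    frames = []
    for i, t in enumerate(tables):
        f = t.df[t.df["weight"] != 0.0][["regulator", "target", "weight"]]
        frames.append(f.rename(columns={"weight": f"w{i}"}))
    merged = frames[0]
    for f in frames[1:]:
        merged = merged.merge(f, on=["regulator", "target"], how="inner")
    wcols = [c for c in merged.columns if c.startswith("w")]
    out = merged[["regulator", "target"]].copy()
    out["weight"] = merged[wcols].mean(axis=1)
    return EdgeTable(out)


def top_fraction_edges(t: EdgeTable, fraction: float) -> EdgeTable:
    """Keep the ceil(fraction * n_nonzero) edges of largest |weight|.

    Ties at the cutoff magnitude are all retained, so the result can exceed
    the nominal count.
    """
    if not 0.0 < fraction <= 1.0:
        raise NetgicError(f"fraction must be in (0, 1], got {fraction}")
    nz = t.nonzero()
    if len(nz) == 0:
        return nz
    k = math.ceil(fraction * len(nz))
    mags = np.abs(nz.df["weight"].to_numpy())
    cutoff = np.sort(mags)[::-1][k - 1]
    keep = nz.df[np.abs(nz.df["weight"]) >= cutoff].reset_index(drop=True)
    return EdgeTable(keep)


def drug_sensitivity_module(sens) -> np.ndarray:
    """First principal-component scores of a samples x drugs sensitivity matrix.

    Columns are mean-centered first.  The sign is fixed so the largest-
    magnitude loading is positive, making the module value reproducible.
    """
    sens = np.asarray(sens, dtype=float)
    if sens.ndim != 2 or sens.shape[1] < 2:
        raise NetgicError("need a samples x drugs matrix with >= 2 drugs")
    if not np.all(np.isfinite(sens)):
        raise NetgicError("sensitivity matrix must not contain missing values")
    centered = sens - sens.mean(axis=0)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    if S[0] == 0:
        raise NetgicError("sensitivity matrix has rank 0 after centering")
    loading = Vt[0]
    if loading[np.argmax(np.abs(loading))] < 0:
        loading, U = -loading, -U
    return U[:, 0] * S[0]


def regulate_effect_change(net: PersonalizedNetwork) -> pd.DataFrame:
    """Range (max - min) of each edge's coefficient across target samples.

    Returns one row per regulator with the per-target ranges and their sum
    (``total``), sorted by total descending; large totals flag regulators
    whose effects change most with the modulator.
    """
    if net.n_target_samples < 2:
        raise NetgicError("need at least 2 target samples to compute a range")
    rng = net.coef.max(axis=2) - net.coef.min(axis=2)   # (target, regulator)
    q = net.n_genes
    rng[np.arange(q), np.arange(q)] = 0.0
    out = pd.DataFrame(rng.T, index=net.gene_ids, columns=net.gene_ids)
    out.index.name = "regulator"
    out.columns.name = "target"
    out["total"] = rng.sum(axis=0)
    return out.sort_values("total", ascending=False)
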