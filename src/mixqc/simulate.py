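"""Labeled synthetic QC metrics and toy count matrices.

The generator mirrors the mixture model's own data-generating story:
each cell is intact or compromised (Bernoulli), draws a library
complexity from a state-specific law, and a mitochondrial percentage
from a state-specific line plus Gaussian noise, clamped to [0, 100].
The latent state is recorded, so classification accuracy and parameter
recovery are directly checkable.  Defaults describe a tumor-like sample
with a substantial compromised fraction: intact cells around 2500
detected genes with a low flat mito line, compromised cells around 800
genes with a high downward-sloping one.

``simulate_count_matrix`` builds a sparse gene-by-cell matrix whose
per-cell totals, detected-gene counts and mito fractions reproduce a
target metrics table, for end-to-end IO tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .qc_metrics import CountMatrix

__all__ = ["SyntheticParams", "simulate_qc_metrics", "simulate_count_matrix"]


@dataclass(frozen=True)
class XLaw:
    """Library-complexity law for one state: lognormal or uniform."""

    kind: str = "lognormal"  # or "uniform"
    a: float = math.log(2500.0)  # meanlog, or low
    b: float = 0.35  # sdlog, or high

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "lognormal":
            x = rng.lognormal(mean=self.a, sigma=self.b, size=n)
        elif self.kind == "uniform":
            x = rng.uniform(self.a, self.b, size=n)
        else:
            raise ValueError(f"unknown x_law kind {self.kind!r}")
        return np.maximum(np.rint(x), 1.0)


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; the defaults are the reference study conditions.

    ``intact`` and ``compromised`` are (intercept, slope, sd) of each
    state's pct-mito line; ``total_factor`` maps detected genes to total
    counts per state.
    """

    n_cells: int = 5000
    pi_compromised: float = 0.25
    intact: tuple[float, float, float] = (1.5, 0.0005, 1.5)
    compromised: tuple[float, float, float] = (45.0, -0.01, 8.0)
    x_law_intact: XLaw = field(default_factory=lambda: XLaw("lognormal", math.log(2500.0), 0.35))
    x_law_compromised: XLaw = field(default_factory=lambda: XLaw("lognormal", math.log(800.0), 0.45))
    # compromised libraries carry fewer reads per detected gene; the factor
    # stays >= 3 so even high-mito cells can give every detected gene a count
    total_factor: tuple[float, float] = (4.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pi_compromised <= 1:
            raise ValueError("pi_compromised must be in [0, 1]")
        if self.intact[2] <= 0 or self.compromised[2] <= 0:
            raise ValueError("noise sds must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticParams":
        d = dict(d)
        for key in ("x_law_intact", "x_law_compromised"):
            if key in d and isinstance(d[key], dict):
                d[key] = XLaw(**d[key])
        for key in ("intact", "compromised", "total_factor"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def simulate_qc_metrics(p: SyntheticParams | None = None) -> pd.DataFrame:
    """Draw a labeled per-cell metrics table.

    Returns the usual metrics columns plus ``true_state`` in
    {"intact", "compromised"}.  Fully reproducible from ``p.seed``.
    """
    if p is None:
        p = SyntheticParams()
    rng = np.random.default_rng(p.seed)
    z = rng.random(p.n_cells) < p.pi_compromised
    x = np.empty(p.n_cells)
    y = np.empty(p.n_cells)
    for state, mask, (b0, b1, sd), law, tf in (
        (0, ~z, p.intact, p.x_law_intact, p.total_factor[0]),
        (1, z, p.compromised, p.x_law_compromised, p.total_factor[1]),
    ):
        n = int(mask.sum())
        if n == 0:
            continue
        xs = law.draw(rng, n)
        ys = b0 + b1 * xs + rng.normal(0.0, sd, size=n)
        x[mask] = xs
        y[mask] = np.clip(ys, 0.0, 100.0)
    factor = np.where(z, p.total_factor[1], p.total_factor[0])
    total = np.rint(x * factor).astype(np.int64)
    return pd.DataFrame(
        {
            "cell_id": [f"cell_{i:05d}" for i in range(p.n_cells)],
            "total_counts": total,
            "detected_genes": x.astype(np.int64),
            "pct_mito": y,
            "zero_total_flag": total == 0,
            "true_state": np.where(z, "compromised", "intact"),
        }
    )


def _fill_cell(
    rng: np.random.Generator,
    total: int,
    detected: int,
    pct: float,
    n_genes: int,
    n_mito: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Gene indices and counts for one cell hitting the target metrics.

    Integer rounding targets the total first, then gives the mito genes
    round(total * pct / 100) counts, as close to the requested fraction
    as integers allow.
    """
    if detected > n_genes:
        raise ValueError(f"target detected_genes {detected} exceeds n_genes {n_genes}")
    if total < detected:
        raise ValueError(
            f"target total_counts {total} < detected_genes {detected}: "
            "every detected gene needs at least one count"
        )
    mito_counts = int(round(total * pct / 100.0))
    if mito_counts > 0 and n_mito == 0:
        raise ValueError("target requires mito counts but n_mito is 0")
    k_mito = min(n_mito, mito_counts, detected)
    k_other = detected - k_mito
    if k_other > n_genes - n_mito:
        raise ValueError("not enough non-mito genes for target detected_genes")
    # each detected gene needs >= 1 count; shave the mito total if rounding
    # left too few counts for the non-mito side (total >= detected makes
    # the result consistent)
    mito_counts = max(min(mito_counts, total - k_other), k_mito)
    mito_genes = rng.choice(n_mito, size=k_mito, replace=False) if k_mito else np.array([], dtype=int)
    other_genes = (
        n_mito + rng.choice(n_genes - n_mito, size=k_other, replace=False)
        if k_other
        else np.array([], dtype=int)
    )

    def split(amount: int, k: int) -> np.ndarray:
        if k == 0:
            return np.array([], dtype=np.int64)
        extra = rng.multinomial(amount - k, np.full(k, 1.0 / k))
        return extra + 1

    counts_m = split(mito_counts, k_mito)
    counts_o = split(total - mito_counts, k_other)
    return np.concatenate([mito_genes, other_genes]), np.concatenate([counts_m, counts_o])


def simulate_count_matrix(
    n_cells: int,
    n_genes: int,
    n_mito: int,
    target: pd.DataFrame | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Sparse gene-by-cell counts reproducing a target metrics table.

    The first ``len(target)`` cells hit the target records' totals,
    detected-gene counts, and mito percentages (up to integer rounding
    of counts); remaining cells are filled with intact-like draws.
    Mitochondrial genes occupy the first ``n_mito`` rows and are named
    with the standard ``MT-`` prefix so pattern matching finds them.
    """
    if n_mito >= n_genes:
        raise ValueError("n_mito must be smaller than n_genes")
    rng = np.random.default_rng(seed)
    if target is None:
        target = pd.DataFrame(columns=["total_counts", "detected_genes", "pct_mito"])
    if len(target) > n_cells:
        raise ValueError("target has more rows than n_cells")

    filler_n = n_cells - len(target)
    if filler_n:
        filler = simulate_qc_metrics(
            SyntheticParams(n_cells=filler_n, pi_compromised=0.0,
                            seed=int(rng.integers(2**31)))
        )
        max_genes = max(n_genes - n_mito, 1)
        filler["detected_genes"] = np.minimum(filler["detected_genes"], max_genes)
        filler["total_counts"] = np.maximum(filler["total_counts"], filler["detected_genes"])
        if n_mito == 0:
            filler["pct_mito"] = 0.0
        spec_rows = pd.concat(
            [target[["total_counts", "detected_genes", "pct_mito"]],
             filler[["total_counts", "detected_genes", "pct_mito"]]],
            ignore_index=True,
        )
    else:
        spec_rows = target[["total_counts", "detected_genes", "pct_mito"]].reset_index(drop=True)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    data: list[np.ndarray] = []
    for j, rec in spec_rows.iterrows():
        g, c = _fill_cell(
            rng,
            int(rec["total_counts"]),
            int(rec["detected_genes"]),
            float(rec["pct_mito"]),
            n_genes,
            n_mito,
        )
        rows.append(g)
        cols.append(np.full(g.size, j, dtype=np.int64))
        data.append(c)

    mat = sparse.coo_matrix(
        (np.concatenate(data) if data else [],
         (np.concatenate(rows) if rows else [], np.concatenate(cols) if cols else [])),
        shape=(n_genes, n_cells),
        dtype=np.int64,
    ).tocsc()
    gene_ids = [f"MT-{i + 1}" for i in range(n_mito)] + [
        f"GENE{i + 1}" for i in range(n_genes - n_mito)
    ]
    cell_ids = (
        [str(c) for c in target["cell_id"]] if "cell_id" in target.columns else []
    )
    cell_ids += [f"cell_{i:05d}" for i in range(len(cell_ids), n_cells)]
    return CountMatrix(values=mat, gene_ids=gene_ids, cell_ids=cell_ids)
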