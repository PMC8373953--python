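"""Cyclic single pairing of lncRNAs into a 0-or-1 matrix.

For an ordered list of k genes, every unordered pair (A, B) with A earlier in
the list yields one feature named ``A|B`` whose value in a sample is 1 iff A's
expression is strictly higher than B's there (ties score 0). Because only the
within-sample ordering matters, the matrix is invariant to any strictly
monotone per-sample transformation of expression — the property that lets the
downstream signature ignore platform- and batch-dependent normalisation.

Pairs that are nearly constant across the cohort carry no ranking
information; the occupancy filter keeps only pairs whose ones-fraction lies
in the [0.20, 0.80] band (inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

OCCUPANCY_LOW_DEFAULT = 0.20
OCCUPANCY_HIGH_DEFAULT = 0.80


@dataclass
class PairMatrix:
    """Binary pairs x samples indicator matrix."""

    pairs: list[tuple[str, str]]
    samples: list[str]
    indicator: np.ndarray  # shape (n_pairs, n_samples), dtype int8, values {0,1}

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=np.int8)
        if self.indicator.shape != (len(self.pairs), len(self.samples)):
            raise ValueError("indicator shape does not match pairs x samples")
        if not np.isin(self.indicator, [0, 1]).all():
            raise ValueError("indicator entries must be 0 or 1")
        if any(a == b for a, b in self.pairs):
            raise ValueError("self-pair (gene_a == gene_b) not allowed")
        unordered = {frozenset(p) for p in self.pairs}
        if len(unordered) != len(self.pairs):
            raise ValueError("duplicate unordered gene pair")

    @property
    def pair_names(self) -> list[str]:
        return [f"{a}|{b}" for a, b in self.pairs]

    @property
    def ones_fraction(self) -> np.ndarray:
        return self.indicator.mean(axis=1)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.indicator, index=self.pair_names, columns=self.samples)

    def subset_pairs(self, keep: np.ndarray) -> "PairMatrix":
        idx = np.flatnonzero(keep) if keep.dtype == bool else np.asarray(keep)
        return PairMatrix(
            pairs=[self.pairs[i] for i in idx],
            samples=list(self.samples),
            indicator=self.indicator[idx],
        )

    def select_named(self, names: list[str]) -> "PairMatrix":
        lookup = {n: i for i, n in enumerate(self.pair_names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"pairs absent from matrix: {missing}")
        return self.subset_pairs(np.array([lookup[n] for n in names]))


def build_pair_matrix(expr: ExpressionMatrix, genes: list[str]) -> PairMatrix:
    """All C(k,2) ordered pairs over ``genes``; earlier gene in the list is gene_a.

    Entry (A|B, s) = 1 iff expr(A, s) > expr(B, s); equal expression scores 0
    under the strict-inequality rule.
    """
    if len(genes) != len(set(genes)):
        raise ValueError("duplicate genes in input list")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    V = expr.values.loc[genes].to_numpy(dtype=float)
    k = len(genes)
    ia, ib = np.triu_indices(k, k=1)
    indicator = (V[ia] > V[ib]).astype(np.int8)
    pairs = [(genes[a], genes[b]) for a, b in zip(ia, ib)]
    return PairMatrix(pairs=pairs, samples=expr.sample_ids, indicator=indicator)


def filter_pairs_by_occupancy(
    pm: PairMatrix,
    low: float = OCCUPANCY_LOW_DEFAULT,
    high: float = OCCUPANCY_HIGH_DEFAULT,
) -> PairMatrix:
    """Keep pairs whose ones-fraction lies in [low, high] (inclusive band).

    The band is symmetric about 0.5, so in the absence of ties retention does
    not depend on pair orientation (f(A|B) = 1 - f(B|A)).
    """
    if low >= high:
        raise ValueError(f"invalid occupancy band: low={low} >= high={high}")
    frac = pm.ones_fraction
    keep = (frac >= low) & (frac <= high)
    out = pm.subset_pairs(keep)
    logger.info("occupancy filter [%g, %g]: kept %d / %d pairs", low, high, out.n_pairs, pm.n_pairs)
    return out


def write_pair_matrix(pm: PairMatrix, path) -> None:
    pm.to_frame().to_csv(path, sep="\t", index_label="pair")
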