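"""Pairwise linkage disequilibrium and co-inheritance block detection.

Works on phased haplotypes coded 0/1 per biallelic site.  For two sites with
allele frequencies ``p_A`` and ``p_B`` and joint haplotype frequency
``p_AB``::

    D  = p_AB - p_A * p_B
    r2 = D**2 / (p_A * p_a * p_B * p_b)
    D' = D / D_max,  D_max = min(p_A*p_b, p_a*p_B) if D > 0
                            else min(p_A*p_B, p_a*p_b)

Blocks are connected components (size >= 2) of the graph with an edge
wherever r2 exceeds the threshold; transitive grouping deliberately lets a
chain of strong pairs bridge one weak pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

MISSING = -1


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes x biallelic sites over {0, 1, missing}.

    ``data`` is an ``(n_haplotypes, n_sites)`` integer array; ``-1`` marks a
    missing call.  ``positions`` give 1-based site coordinates used for block
    ordering; ``populations`` labels each haplotype row.
    """

    data: np.ndarray
    site_ids: list[str]
    positions: list[int] | None = None
    populations: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise ValueError("haplotype data must be 2-dimensional")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.data.shape[1] != len(self.site_ids):
            raise ValueError("site_ids length does not match data columns")
        bad = ~np.isin(self.data, [0, 1, MISSING])
        if bad.any():
            raise ValueError("haplotype codes must be 0, 1 or -1 (missing)")
        if self.positions is None:
            self.positions = list(range(1, self.data.shape[1] + 1))
        if self.populations is None:
            self.populations = ["pop0"] * self.data.shape[0]
        if len(self.populations) != self.data.shape[0]:
            raise ValueError("populations length does not match haplotype count")

    @property
    def n_haplotypes(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def subset_population(self, population: str) -> "HaplotypeMatrix":
        mask = np.array([p == population for p in self.populations])
        return HaplotypeMatrix(
            self.data[mask], list(self.site_ids), list(self.positions),
            [p for p in self.populations if p == population],
        )


@dataclass(frozen=True)
class LDPair:
    """LD statistics for one unordered site pair (``None`` when undefined)."""

    d: float | None
    d_prime: float | None
    r2: float | None
    n_used: int
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None


@dataclass
class LDMatrixResult:
    """Square r2 and D' matrices plus the per-pair detail map."""

    site_ids: list[str]
    positions: list[int]
    r2: np.ndarray
    d_prime: np.ndarray
    pairs: dict[tuple[int, int], LDPair] = field(default_factory=dict)


def _pair_stats(x: np.ndarray, y: np.ndarray) -> LDPair:
    keep = (x != MISSING) & (y != MISSING)
    n = int(keep.sum())
    if n == 0:
        return LDPair(None, None, None, 0, "no haplotypes with both sites called")
    x, y = x[keep].astype(float), y[keep].astype(float)
    p_a, p_b = x.mean(), y.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LDPair(None, None, None, n, "monomorphic site in pairwise-complete haplotypes")
    p_ab = float((x * y).mean())
    d = p_ab - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = d * d / denom
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = d / d_max if d_max > 0 else 0.0
    return LDPair(d, d_prime, r2, n)


def pairwise_ld(hap: HaplotypeMatrix, i: int, j: int) -> LDPair:
    """LD statistics between site columns ``i`` and ``j``.

    Haplotypes missing at either site are dropped pairwise.  Monomorphic
    sites yield an undefined result (with reason), not an exception.
    """
    return _pair_stats(hap.data[:, i], hap.data[:, j])


def ld_matrix(hap: HaplotypeMatrix) -> LDMatrixResult:
    """All-pairs LD; diagonal r2 is 1 for polymorphic sites, NaN otherwise."""
    n = hap.n_sites
    r2 = np.full((n, n), np.nan)
    dp = np.full((n, n), np.nan)
    pairs: dict[tuple[int, int], LDPair] = {}
    for i in range(n):
        col = hap.data[:, i]
        called = col[col != MISSING]
        if called.size and 0 < called.mean() < 1:
            r2[i, i] = 1.0
            dp[i, i] = 1.0
    for i in range(n):
        for j in range(i + 1, n):
            pair = _pair_stats(hap.data[:, i], hap.data[:, j])
            pairs[(i, j)] = pair
            if pair.defined:
                r2[i, j] = r2[j, i] = pair.r2
                dp[i, j] = dp[j, i] = pair.d_prime
    return LDMatrixResult(list(hap.site_ids), list(hap.positions), r2, dp, pairs)


def detect_blocks(ld: LDMatrixResult, threshold: float = 0.8) -> list[list[str]]:
    """Co-inheritance blocks at the given r2 threshold.

    Returns connected components (size >= 2) of the r2 > threshold graph as
    lists of site_ids, each block and the block list ordered by position.
    """
    n = len(ld.site_ids)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            v = ld.r2[i, j]
            if np.isfinite(v) and v > threshold:
                g.add_edge(i, j)
    blocks = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        members = sorted(comp, key=lambda k: ld.positions[k])
        blocks.append([ld.site_ids[k] for k in members])
    blocks.sort(key=lambda b: ld.positions[ld.site_ids.index(b[0])])
    return blocks


def ld_pairs_frame(ld: LDMatrixResult):
    """Long-format pair table (site_a, site_b, D, D', r2, n_used) for export."""
    import pandas as pd

    rows = []
    for (i, j), pair in sorted(ld.pairs.items()):
        rows.append({
            "site_a": ld.site_ids[i], "site_b": ld.site_ids[j],
            "d": pair.d, "d_prime": pair.d_prime, "r2": pair.r2,
            "n_used": pair.n_used, "undefined_reason": pair.undefined_reason or "",
        })
    return pd.DataFrame(rows, columns=["site_a", "site_b", "d", "d_prime", "r2",
                                       "n_used", "undefined_reason"])
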