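"""Selection of divergent-but-interacting paralog pairs (DIRPs).

A paralog pair enters the DIRP set of a given (network, kernel) combination
when

* its pairwise sequence identity over mutually non-gap alignment columns is at
  most ``identity_max_pct`` (default 45%, the regime BLOSUM45 was designed
  for; the corresponding normalised phylogenetic distance boundary, about 1.7,
  is kept as an optional secondary gate); and
* its kernel similarity in the real network is at least the ``1 - alpha``
  empirical quantile (default alpha = 0.05) of the similarity distribution
  observed on degree-preserving network randomisations.

Pairs that become unreachable after hub removal (different components) are
excluded from candidacy and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import GAP, MultipleAlignment
from .network import DEFAULT_HUB_DEGREE_CUTOFF
from .randomization import NullEnsemble

__all__ = [
    "ParalogPair",
    "PipelineConfig",
    "DIRPSet",
    "pairwise_identity",
    "closeness_threshold",
    "select_dirp",
    "shared_partner_stats",
    "bin_distance_summary",
]


@dataclass
class PipelineConfig:
    """Thresholds of the scan, with the field-standard defaults."""

    identity_max_pct: float = 45.0
    phylo_norm_min: float = 1.7
    closeness_alpha: float = 0.05
    conservation_alpha: float = 0.01
    hub_degree_cutoff: int = DEFAULT_HUB_DEGREE_CUTOFF
    diffusion_beta: float = 1.0
    null_replicates: int = 100
    phylo_lambda: float = 1.0
    delta_sasa_min: float = 1.0
    use_phylo_gate: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.identity_max_pct <= 100:
            raise ValueError("identity_max_pct must be in [0, 100]")
        if not 0 < self.closeness_alpha < 1:
            raise ValueError("closeness_alpha must be in (0, 1)")
        if not 0 < self.conservation_alpha <= 1:
            raise ValueError("conservation_alpha must be in (0, 1]")
        if self.hub_degree_cutoff < 1:
            raise ValueError("hub_degree_cutoff must be >= 1")


@dataclass(frozen=True)
class ParalogPair:
    """One paralog pair with its sequence, tree and network coordinates."""

    id_a: str
    id_b: str
    identity_pct: float
    phylo_norm: float = np.nan
    similarity: dict = field(default_factory=dict)  # kernel kind -> K_ab
    net_dist: dict = field(default_factory=dict)  # kernel kind -> -ln(p)
    reachable: bool = True

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.id_a, self.id_b)))


@dataclass(frozen=True)
class DIRPSet:
    """Selected pairs for one (network, kernel) combination, with provenance."""

    pairs: tuple[ParalogPair, ...]
    kernel: str
    cutoff: float
    network: str = ""
    config: PipelineConfig | None = None
    n_candidates: int = 0
    n_after_identity: int = 0
    n_unreachable: int = 0

    def keys(self) -> list[tuple[str, str]]:
        return [p.key for p in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)


def pairwise_identity(msa: MultipleAlignment, id_a: str, id_b: str) -> float:
    """Percent identical residues over columns where both rows are non-gap."""
    sa, sb = msa[id_a], msa[id_b]
    comparable = same = 0
    for ca, cb in zip(sa, sb):
        if ca == GAP or cb == GAP:
            continue
        comparable += 1
        if ca == cb:
            same += 1
    if comparable == 0:
        raise ValueError(f"no mutually non-gap columns between {id_a} and {id_b}")
    return 100.0 * same / comparable


def closeness_threshold(null: NullEnsemble, alpha: float = 0.05) -> float:
    """Similarity cutoff: the (1 - alpha) empirical quantile of the null.

    Uses the linear-interpolation (type-7) quantile convention; ``alpha = 0``
    returns the null maximum.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    return float(np.quantile(null.values, 1.0 - alpha, method="linear"))


def select_dirp(
    pairs: list[ParalogPair],
    cfg: PipelineConfig,
    cutoff: float,
    kernel: str,
    network: str = "",
) -> DIRPSet:
    """Apply the identity and network-closeness thresholds for one kernel."""
    unreachable = [p for p in pairs if not p.reachable]
    candidates = [p for p in pairs if p.reachable]
    divergent = [p for p in candidates if p.identity_pct <= cfg.identity_max_pct]
    if cfg.use_phylo_gate:
        divergent = [
            p for p in divergent
            if not np.isfinite(p.phylo_norm) or p.phylo_norm > cfg.phylo_norm_min
        ]
    selected = []
    for p in divergent:
        if kernel not in p.similarity:
            raise ValueError(f"pair {p.key} lacks a {kernel!r} similarity value")
        if p.similarity[kernel] >= cutoff:
            selected.append(p)
    return DIRPSet(
        pairs=tuple(selected),
        kernel=kernel,
        cutoff=float(cutoff),
        network=network,
        config=cfg,
        n_candidates=len(candidates),
        n_after_identity=len(divergent),
        n_unreachable=len(unreachable),
    )


def shared_partner_stats(
    net: nx.Graph, pairs: list[tuple[str, str]]
) -> tuple[pd.DataFrame, float]:
    """Shared-interactor count |N(a) ∩ N(b)| per pair (excluding a, b) + median."""
    rows = []
    for a, b in pairs:
        if a not in net or b not in net:
            raise KeyError(f"pair member absent from network: {a if a not in net else b}")
        shared = (set(net[a]) & set(net[b])) - {a, b}
        rows.append((a, b, len(shared)))
    frame = pd.DataFrame(rows, columns=["id_a", "id_b", "n_shared"])
    median = float(frame["n_shared"].median()) if len(frame) else np.nan
    return frame, median


def bin_distance_summary(
    pairs: list[ParalogPair],
    kernel: str,
    n_bins: int = 4,
    null_pairs: list[ParalogPair] | None = None,
) -> pd.DataFrame:
    """Five-number summaries of network distance by normalised-phylo-distance bin.

    Bin edges are equal-width over the observed phylo range; an optional null
    pair list (e.g. from rewired networks) is summarised in the same bins.
    """
    def summarize(values: np.ndarray) -> dict:
        if values.size == 0:
            return dict(n=0, min=np.nan, q1=np.nan, median=np.nan, q3=np.nan, max=np.nan)
        q = np.quantile(values, [0, 0.25, 0.5, 0.75, 1])
        return dict(n=int(values.size), min=q[0], q1=q[1], median=q[2], q3=q[3], max=q[4])

    usable = [p for p in pairs if p.reachable and np.isfinite(p.phylo_norm)]
    phylo = np.array([p.phylo_norm for p in usable])
    edges = np.linspace(phylo.min(), phylo.max(), n_bins + 1) if usable else np.arange(n_bins + 1.0)
    rows = []
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        def in_bin(plist):
            sel = [
                p.net_dist[kernel]
                for p in plist
                if p.reachable
                and np.isfinite(p.phylo_norm)
                and (lo <= p.phylo_norm < hi or (i == n_bins - 1 and p.phylo_norm == hi))
            ]
            return np.array(sel, dtype=float)
        row = dict(bin=i, lo=lo, hi=hi, **summarize(in_bin(pairs)))
        if null_pairs is not None:
            row.update({f"null_{k}": v for k, v in summarize(in_bin(null_pairs)).items()})
        rows.append(row)
    return pd.DataFrame(rows)
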