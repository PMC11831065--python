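"""Group-level thresholded coherence graphs and significant-difference graphs.

A group graph connects channel pairs whose *median* coherence over the
group's subjects reaches a threshold (0.5 for meaningful, 0.7 for robust
connections by default).  A difference graph marks pairs that are
FDR-significant with the case-group median *below* the control median
(case-deficit direction); significant pairs in the opposite direction are
kept separately and logged.

Region summaries count difference edges per (region, region) cell of the
montage's scalp-region tagging, normalised by the number of available pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DataError
from .group_stats import EdgeTestResult
from .montage import Montage
from .spectral import CoherenceProfile

logger = logging.getLogger(__name__)


@dataclass
class GroupGraph:
    """Thresholded median-coherence graph of one group/condition/band."""

    group: str
    condition: str
    band: str
    threshold: float
    channels: tuple[str, ...]
    median_matrix: np.ndarray
    edges: set[tuple[str, str]] = field(default_factory=set)

    def to_networkx(self):
        """The thresholded graph as a networkx.Graph with median edge weights."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.channels)
        idx = {c: i for i, c in enumerate(self.channels)}
        for a, b in sorted(self.edges):
            g.add_edge(a, b, median=float(self.median_matrix[idx[a], idx[b]]))
        return g


@dataclass
class DifferenceGraph:
    """FDR-significant case-deficit edges of one condition/band.

    ``edges`` maps each significant case-deficit pair to its q-value;
    ``reversed_edges`` holds significant pairs where the case median exceeds
    the control median (reported, not part of the deficit graph).
    """

    condition: str
    band: str
    q_cutoff: float
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    reversed_edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)


def group_median(
    profiles: list[CoherenceProfile], group: str, condition: str, band: str
) -> np.ndarray:
    """Element-wise median coherence matrix across a group's subjects.

    Even subject counts take the midpoint of the two central order
    statistics (numpy convention).
    """
    sel = [p for p in profiles if p.group == group and p.condition == condition]
    if not sel:
        raise DataError(f"no profiles for group={group}, condition={condition}")
    channels = sel[0].channels
    if any(p.channels != channels for p in sel):
        raise DataError("profiles have mismatched channel lists")
    return np.median(np.stack([p.band_matrices[band] for p in sel]), axis=0)


def threshold_graph(
    median_matrix: np.ndarray,
    threshold: float,
    channels: tuple[str, ...],
    group: str = "",
    condition: str = "",
    band: str = "",
) -> GroupGraph:
    """Edges where the median coherence is at or above the threshold (i < j)."""
    if not 0 <= threshold <= 1:
        raise ConfigurationError("threshold must lie in [0, 1]")
    m = np.asarray(median_matrix)
    edges = {
        (channels[i], channels[j])
        for i in range(len(channels))
        for j in range(i + 1, len(channels))
        if m[i, j] >= threshold
    }
    return GroupGraph(
        group=group, condition=condition, band=band, threshold=threshold,
        channels=tuple(channels), median_matrix=m, edges=edges,
    )


def difference_graph(
    test_results: list[EdgeTestResult], q_cutoff: float = 0.05
) -> DifferenceGraph:
    """Significant case-deficit edges (q <= cutoff and case median < control).

    Medians are taken from the test results themselves, so the function needs
    no separate median matrices; significant case-excess pairs are logged and
    returned in ``reversed_edges``.
    """
    if not 0 < q_cutoff < 1:
        raise ConfigurationError("q_cutoff must lie in (0, 1)")
    if not test_results:
        raise DataError("no test results supplied")
    band = test_results[0].band
    condition = test_results[0].condition
    dg = DifferenceGraph(condition=condition, band=band, q_cutoff=q_cutoff)
    for r in test_results:
        if r.q <= q_cutoff:
            if r.case_deficit:
                dg.edges[r.pair] = r.q
            else:
                dg.reversed_edges[r.pair] = r.q
    if dg.reversed_edges:
        logger.info(
            "%s/%s: %d significant case-excess edges (opposite direction): %s",
            band, condition, len(dg.reversed_edges), sorted(dg.reversed_edges),
        )
    return dg


def region_summary(dg: DifferenceGraph, montage: Montage) -> dict[tuple[str, str], dict]:
    """Difference-edge counts and densities per (region, region) cell.

    For every unordered region pair (including within-region cells) returns
    ``{"count": ..., "available": ..., "density": count/available}``; cells
    with no available channel pair have density 0.
    """
    region_of = dict(zip(montage.labels, montage.regions))
    for a, b in itertools.chain(dg.edges, dg.reversed_edges):
        if a not in region_of or b not in region_of:
            raise DataError(f"edge channel without region tag: {a}/{b}")

    present = sorted(set(montage.regions))
    out: dict[tuple[str, str], dict] = {}
    for ra, rb in itertools.combinations_with_replacement(present, 2):
        key = (ra, rb)
        chans_a = [c for c in montage.labels if region_of[c] == ra]
        chans_b = [c for c in montage.labels if region_of[c] == rb]
        if ra == rb:
            available = len(chans_a) * (len(chans_a) - 1) // 2
        else:
            available = len(chans_a) * len(chans_b)
        count = 0
        for a, b in dg.edges:
            pair_regions = tuple(sorted((region_of[a], region_of[b])))
            if pair_regions == tuple(sorted(key)):
                count += 1
        out[key] = {
            "count": count,
            "available": available,
            "density": count / available if available else 0.0,
        }
    return out
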