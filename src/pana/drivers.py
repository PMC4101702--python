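"""Driving-gene identification via a density-valley loading cutoff.

Loadings of a pathway profile measure each gene's contribution to the
profile. In typical PCA models most genes have near-zero loadings and a
small subset carries the component, so the distribution of absolute
loadings is at least bimodal: a tall mode of negligible values and one or
more modes of important ones. The cutoff separating them is found by
estimating the density of |loadings| with a Gaussian kernel (Silverman
bandwidth) and taking the abscissa of the first local minimum scanning
from zero — the valley after the first mode. Genes above the cutoff are
the profile's *driving genes*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .compression import ProfileSet

__all__ = ["DrivingGeneReport", "minas_cutoff", "driving_genes"]

GRID_POINTS = 512


@dataclass
class DrivingGeneReport:
    profile_id: str
    cutoff: float | None                       # None when no bimodality found
    driving_genes: list[tuple[str, float]]     # (gene, loading), |loading| desc
    flag: str = ""                             # '' | 'no bimodality'


def minas_cutoff(values) -> float | None:
    """First density-valley cutoff of a nonnegative statistic.

    Estimates the density of ``values`` with a Gaussian KDE (Silverman's
    bandwidth) on a 512-point grid over [0, 1.05 * max] and returns the
    abscissa of the first interior local minimum scanning upward from
    zero, i.e. the valley after the first mode. Returns ``None`` when the
    density is unimodal on the grid. Plateaus resolve to their leftmost
    point.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("minAS needs at least 5 values")
    if (v < 0).any():
        raise ValueError("minAS expects nonnegative values")
    if np.ptp(v) == 0:
        return None
    kde = stats.gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(0.0, float(v.max()) * 1.05, GRID_POINTS)
    dens = kde(grid)
    d = np.diff(dens)
    # a valley = fall then rise; a rise can only follow the first mode, so
    # the first such point is the wanted cutoff. Exact plateaus resolve to
    # their leftmost point (first non-falling step after a fall).
    fell_at: int | None = None
    for i in range(1, GRID_POINTS - 1):
        if d[i - 1] < 0:
            fell_at = i
        elif d[i - 1] > 0:
            if fell_at is not None:
                return float(grid[fell_at])
            fell_at = None
    return None


def driving_genes(profile_set: ProfileSet, profile: str) -> DrivingGeneReport:
    """Driving genes of one profile: |loading| above the minAS cutoff.

    Falls back to the single top-|loading| gene (flagged 'no bimodality')
    when the loading density is unimodal or the pathway is too small for a
    density estimate. Absolute loadings make the result invariant to the
    PC sign convention.
    """
    p = profile_set.get(profile)
    absl = np.abs(p.loadings)
    cutoff: float | None = None
    if absl.size >= 5:
        cutoff = minas_cutoff(absl)
    if cutoff is None:
        top = int(np.argmax(absl))
        return DrivingGeneReport(
            profile_id=profile, cutoff=None,
            driving_genes=[(p.gene_ids[top], float(p.loadings[top]))],
            flag="no bimodality")
    order = np.argsort(-absl)
    drivers = [(p.gene_ids[i], float(p.loadings[i]))
               for i in order if absl[i] > cutoff]
    if not drivers:
        top = int(order[0])
        return DrivingGeneReport(profile, None,
                                 [(p.gene_ids[top], float(p.loadings[top]))],
                                 "no bimodality")
    return DrivingGeneReport(profile, float(cutoff), drivers)


def all_driving_genes(profile_set: ProfileSet) -> dict[str, DrivingGeneReport]:
    return {pid: driving_genes(profile_set, pid)
            for pid in profile_set.profile_ids}


def write_drivers(reports: dict[str, DrivingGeneReport], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("profile_id\tgene_id\tloading\tcutoff\tflag\n")
        for pid, rep in reports.items():
            cut = "" if rep.cutoff is None else f"{rep.cutoff:.10g}"
            for gene, loading in rep.driving_genes:
                fh.write(f"{pid}\t{gene}\t{loading:.10g}\t{cut}\t{rep.flag}\n")
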