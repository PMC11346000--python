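"""Gating scheme for Ki67 positivity in dissociated FFPE nuclei.

The chain mirrors how the assay is analysed on a cytometer:

1. **DNA-content gate** — locate the dominant (2n) peak of the DNA-dye
   histogram, keep events at the peak and above it (``2n`` and ``>=2n``),
   discard sub-2n debris, and report QC rates.
2. **Isotype percentile cutoffs** — every positivity threshold is the q-th
   percentile (default 95) of the isotype-matched control under the same
   gate chain; an event is positive only when *strictly above* the cutoff.
3. **Population gate** — either a cytokeratin gate (CK channel above its
   isotype cutoff) or the biomarker-free **AreaX** ellipse on FSC–SSC,
   fitted so that it contains the CK-positive main population (the
   highest-density region holding ~40% of events) while excluding the
   CK-negative one (dominated by lymphocyte nuclei, which are smaller).
4. **Ki67 positivity** — percentage of gated events above the Ki67 cutoff.

Determinism: kernel bandwidths follow Scott's rule, histograms live on fixed
grids (256 bins for the 1-D DNA chart, 128x128 for FSC-SSC), and all
tie-breaks are documented, so a given sample always yields the same gates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from scipy.stats import gaussian_kde

from .io import EventTable, SamplePair

__all__ = [
    "DnaGate",
    "DnaPartition",
    "QcRates",
    "PercentileCutoff",
    "EllipseGate",
    "GateSet",
    "HdrResult",
    "GateInfeasibleError",
    "find_2n_peak",
    "dna_partition",
    "qc_rates",
    "percentile_cutoff",
    "positivity",
    "ck_gate",
    "main_population",
    "fit_areax",
    "apply_gate",
    "ki67_positivity",
    "Ki67Result",
]

SCHEMES = ("dapi_only", "ck", "areax")


class GateInfeasibleError(RuntimeError):
    """The CK+ and CK- populations overlap too much for an exclusion gate."""


# ---------------------------------------------------------------------------
# DNA-content gate and QC


@dataclass(frozen=True)
class DnaGate:
    """Window around the 2n peak: bounds ``peak*(1-w)`` .. ``peak*(1+w)``.

    ``w`` defaults to 0.2, wide enough for DAPI staining CV without
    swallowing the 4n peak at twice the 2n position.
    """

    peak_2n: float
    window_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not self.peak_2n > 0:
            raise ValueError("peak_2n must be positive")
        if not 0 < self.window_fraction < 1:
            raise ValueError("window_fraction must be in (0, 1)")

    @property
    def lower(self) -> float:
        return self.peak_2n * (1 - self.window_fraction)

    @property
    def upper(self) -> float:
        return self.peak_2n * (1 + self.window_fraction)


@dataclass(frozen=True)
class DnaPartition:
    """Exhaustive, disjoint split of events by DNA content.

    ``analysis`` (the positivity denominator gate) is ``at_2n | above_2n``,
    i.e. the "2n peak and more than 2n" region; aggregates are retained on
    purpose — there is no pulse-geometry doublet discrimination in this
    assay.
    """

    below_2n: np.ndarray
    at_2n: np.ndarray
    above_2n: np.ndarray

    @property
    def analysis(self) -> np.ndarray:
        return self.at_2n | self.above_2n


@dataclass(frozen=True)
class QcRates:
    """Dissociation quality rates derived from the DNA partition."""

    cell_recovery_rate: float   # percent: 2n / total x 100
    debris_rate: float          # ratio:   <2n / 2n
    single_cell_rate: float     # percent: 2n / >=2n x 100


def find_2n_peak(table: EventTable, grid_size: int = 256,
                 min_events: int = 100) -> float:
    """Location of the dominant DNA-histogram mode (the 2n peak).

    The mode is taken from a Gaussian KDE (Scott's rule) evaluated on a
    ``grid_size``-point grid spanning ``[0, max*1.05]``.  In a 2n-dominant
    sample this is the G0/G1 diploid peak.  A degenerate (all-equal) channel
    returns that value with a warning, as does a very small sample.
    """
    values = table.channel("DNA")
    if values.size == 0:
        raise ValueError("cannot locate a 2n peak in an empty table")
    if values.size < min_events:
        warnings.warn(
            f"only {values.size} events; 2n peak location may be unstable",
            stacklevel=2,
        )
    if np.ptp(values) == 0:
        warnings.warn("degenerate DNA channel (all events equal)", stacklevel=2)
        return float(values[0])
    grid = np.linspace(0.0, values.max() * 1.05, grid_size)
    density = gaussian_kde(values, bw_method="scott")(grid)
    return float(grid[int(np.argmax(density))])


def dna_partition(table: EventTable, gate: DnaGate) -> DnaPartition:
    """Split events into sub-2n debris, the 2n window, and above-2n."""
    dna = table.channel("DNA")
    below = dna < gate.lower
    at = (dna >= gate.lower) & (dna <= gate.upper)
    above = dna > gate.upper
    return DnaPartition(below_2n=below, at_2n=at, above_2n=above)


def qc_rates(partition: DnaPartition) -> QcRates:
    """Quality rates: recovery = 2n/total x 100, debris = <2n/2n,
    single-cell = 2n/>=2n x 100.  Zero denominators raise."""
    n_below = int(partition.below_2n.sum())
    n_at = int(partition.at_2n.sum())
    n_above = int(partition.above_2n.sum())
    total = n_below + n_at + n_above
    if total == 0:
        raise ValueError("cell_recovery_rate undefined: empty partition")
    if n_at == 0:
        raise ValueError("debris_rate undefined: no events in the 2n window")
    return QcRates(
        cell_recovery_rate=100.0 * n_at / total,
        debris_rate=n_below / n_at,
        single_cell_rate=100.0 * n_at / (n_at + n_above),
    )


# ---------------------------------------------------------------------------
# Percentile cutoffs and positivity


@dataclass(frozen=True)
class PercentileCutoff:
    """A channel threshold set at the q-th percentile of an isotype control.

    The percentile uses linear interpolation between order statistics
    (``numpy.percentile`` default), the convention of common cytometry
    software.
    """

    role: str
    q: float
    threshold: float

    def __post_init__(self) -> None:
        if not 0 < self.q < 100:
            raise ValueError("q must be in (0, 100)")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def percentile_cutoff(control: EventTable, role: str, q: float = 95.0,
                      mask: np.ndarray | None = None) -> PercentileCutoff:
    """Fit a percentile cutoff on the control sample's ``role`` channel.

    ``mask`` restricts the control to the same analysis gate applied to the
    stained sample, so background is measured in the population actually
    scored.
    """
    if control.stain != "isotype_control":
        raise ValueError(
            f"cutoffs must come from an isotype control, got stain "
            f"{control.stain!r}"
        )
    values = control.channel(role)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    if values.size == 0:
        raise ValueError(f"no control events to fit the {role} cutoff")
    return PercentileCutoff(role=role, q=q,
                            threshold=float(np.percentile(values, q)))


def positivity(stained: EventTable, cutoff: PercentileCutoff,
               mask: np.ndarray | None = None) -> float:
    """Percent of gated events strictly above the cutoff.

    Strict ``>``: an event equal to the threshold is negative, so a cutoff
    that coincides with a control event never counts that event positive.
    """
    values = stained.channel(cutoff.role)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    if values.size == 0:
        raise ValueError("positivity undefined on an empty gate")
    return 100.0 * float(np.mean(values > cutoff.threshold))


def ck_gate(pair: SamplePair, gate: DnaGate, q: float = 95.0) -> np.ndarray:
    """Boolean mask of stained events passing DNA analysis + CK cutoff.

    The CK cutoff is the q-th percentile of the control's CK channel within
    the control's own DNA analysis gate.  An empty result is not an error —
    a sample may simply contain no CK-positive nuclei.
    """
    stained_part = dna_partition(pair.stained, gate)
    control_part = dna_partition(pair.control, gate)
    cutoff = percentile_cutoff(pair.control, "CK", q=q,
                               mask=control_part.analysis)
    return stained_part.analysis & (pair.stained.channel("CK") > cutoff.threshold)


# ---------------------------------------------------------------------------
# Highest-density region ("main population") on FSC-SSC


@dataclass(frozen=True)
class HdrResult:
    """Highest-density region of a 2-D point cloud on a fixed grid.

    ``cells`` is the boolean grid-cell membership; the region is the union
    of grid cells, accumulated in decreasing order of smoothed density until
    at least ``mass`` of the events is covered.
    """

    cells: np.ndarray            # (grid, grid) bool
    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray          # smoothed density used for ranking
    mass: float
    covered_fraction: float
    n_events: int

    @property
    def area(self) -> float:
        dx = np.diff(self.x_edges)[0]
        dy = np.diff(self.y_edges)[0]
        return float(self.cells.sum() * dx * dy)

    def cell_centers(self) -> np.ndarray:
        """(m, 2) coordinates of the centers of the occupied HDR cells."""
        cx = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        cy = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        ix, iy = np.nonzero(self.cells)
        return np.column_stack([cx[ix], cy[iy]])

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership of arbitrary points in the HDR cell union."""
        points = np.asarray(points, dtype=float)
        ix = np.searchsorted(self.x_edges, points[:, 0], side="right") - 1
        iy = np.searchsorted(self.y_edges, points[:, 1], side="right") - 1
        inside = (
            (ix >= 0) & (ix < self.cells.shape[0])
            & (iy >= 0) & (iy < self.cells.shape[1])
        )
        out = np.zeros(len(points), dtype=bool)
        out[inside] = self.cells[ix[inside], iy[inside]]
        return out


def _scott_sigma_bins(values: np.ndarray, bin_width: float) -> float:
    """Scott's-rule 2-D bandwidth for one margin, in units of grid bins."""
    n = values.size
    h = values.std(ddof=1) * n ** (-1.0 / 6.0)
    return max(h / bin_width, 1e-9)


def main_population(points: np.ndarray, mass: float = 0.40,
                    grid_size: int = 128, min_events: int = 500) -> HdrResult:
    """Highest-density region holding ``mass`` of the events.

    Events are binned on a fixed ``grid_size``-squared grid spanning
    ``[min(0, data), max*1.05]`` per axis; the histogram is smoothed with a
    Gaussian kernel (Scott's rule) and grid cells are accumulated in
    decreasing density order (ties broken by cell index) until at least
    ``mass`` of the events is covered.  With ``mass`` = 0.40 this is the
    "main population" of a scatterplot — the region where about 40% of the
    nuclei concentrate.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(points)
    if n == 0:
        raise ValueError("cannot compute an HDR of zero events")
    if n < min_events:
        warnings.warn(f"only {n} events; HDR may be unstable", stacklevel=2)

    x, y = points[:, 0], points[:, 1]
    x_edges = np.linspace(min(0.0, x.min() * 1.05), x.max() * 1.05, grid_size + 1)
    y_edges = np.linspace(min(0.0, y.min() * 1.05), y.max() * 1.05, grid_size + 1)
    counts, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])

    sx = _scott_sigma_bins(x, np.diff(x_edges)[0])
    sy = _scott_sigma_bins(y, np.diff(y_edges)[0])
    density = ndimage.gaussian_filter(counts, sigma=(sx, sy), mode="constant")

    order = np.argsort(-density.ravel(), kind="stable")
    cum = np.cumsum(counts.ravel()[order])
    target = mass * n
    k = int(np.searchsorted(cum, target)) + 1
    cells = np.zeros(density.size, dtype=bool)
    cells[order[:k]] = True
    cells = cells.reshape(density.shape)
    return HdrResult(
        cells=cells, x_edges=x_edges, y_edges=y_edges, density=density,
        mass=mass, covered_fraction=float(cum[k - 1] / n), n_events=n,
    )


# ---------------------------------------------------------------------------
# AreaX ellipse gate


@dataclass(frozen=True)
class EllipseGate:
    """Elliptical FSC-SSC gate (the "AreaX" of this assay).

    Membership is the closed quadratic-form test after centering and
    rotation; boundary events are members.  ``provenance`` records the
    training samples, HDR mass and fitting diagnostics that produced the
    gate so a frozen gate file is self-describing.
    """

    center: tuple
    semi_axes: tuple
    angle: float                      # radians, first axis vs. FSC axis
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not all(a > 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, s], [-s, c]])
        local = (points - np.asarray(self.center)) @ rot.T
        q = (local[:, 0] / self.semi_axes[0]) ** 2 \
            + (local[:, 1] / self.semi_axes[1]) ** 2
        return q <= 1.0 + 1e-12

    def to_dict(self) -> dict:
        return {
            "center": [float(v) for v in self.center],
            "semi_axes": [float(v) for v in self.semi_axes],
            "angle": float(self.angle),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EllipseGate":
        return cls(center=tuple(d["center"]), semi_axes=tuple(d["semi_axes"]),
                   angle=float(d["angle"]), provenance=dict(d.get("provenance", {})))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "EllipseGate":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def apply_gate(events, ellipse: EllipseGate) -> np.ndarray:
    """Boolean FSC-SSC membership of an event table (or (n,2) array)."""
    points = events.scatter() if isinstance(events, EventTable) else events
    return ellipse.contains(points)


def fit_areax(ck_pos: np.ndarray, ck_neg: np.ndarray | None,
              mass: float = 0.40, retain: float = 0.99,
              coverage_floor: float = 0.50, grid_size: int = 128) -> EllipseGate:
    """Fit the AreaX ellipse from CK-positive and CK-negative scatter points.

    Procedure: the main population (HDR at ``mass``) of the CK+ events fixes
    center and orientation through Gaussian moments of the events inside it.
    Estimating moments on the HDR core makes the fit robust to CK+ events
    far from the main population (aggregates, outliers), but truncation
    shrinks the covariance; for a Gaussian truncated at its ``mass``-HDR
    contour the shrinkage has the closed form ``k = (2 - (t+2) e^{-t/2}) /
    (2 (1 - e^{-t/2}))`` with ``t = -2 ln(1-mass)`` (the chi-square(2)
    quantile), so the core covariance is divided by ``k`` to recover the
    population covariance.  The ellipse level is then the larger of (a) the
    smallest level containing all CK+ HDR cell centers and (b) the
    chi-square(2) ``retain`` quantile — so the gate holds the bulk of the
    CK+ population, not merely its densest core.  If the CK- HDR intrudes,
    the level is shrunk to just exclude every CK- HDR cell center; if that
    would leave less than ``coverage_floor`` of the CK+ HDR inside, the
    populations are declared inseparable and :class:`GateInfeasibleError`
    is raised with overlap diagnostics.

    By construction the returned gate is disjoint from the CK- HDR (its
    cell centers), in either branch.
    """
    ck_pos = np.asarray(ck_pos, dtype=float)
    if len(ck_pos) == 0:
        raise ValueError("CK-positive point set is empty")
    hdr_pos = main_population(ck_pos, mass=mass, grid_size=grid_size)

    inside = hdr_pos.contains(ck_pos)
    core = ck_pos[inside]
    mu = core.mean(axis=0)
    t = -2.0 * np.log1p(-mass)  # chi2(2 df) quantile at `mass`
    shrink = (2.0 - (t + 2.0) * np.exp(-t / 2.0)) / (2.0 * (1.0 - np.exp(-t / 2.0)))
    sigma = np.cov(core, rowvar=False) / shrink
    sigma_inv = np.linalg.inv(sigma)

    def qform(pts: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(pts) - mu
        return np.einsum("ij,jk,ik->i", d, sigma_inv, d)

    pos_centers = hdr_pos.cell_centers()
    c_hdr = float(qform(pos_centers).max())
    c_retain = float(-2.0 * np.log1p(-retain))  # chi2(2 df) quantile
    c = max(c_hdr, c_retain)

    diagnostics = {"mass": mass, "retain": retain, "c_hdr": c_hdr,
                   "c_retain": c_retain, "n_pos": int(len(ck_pos))}
    if ck_neg is not None and len(ck_neg):
        hdr_neg = main_population(np.asarray(ck_neg, dtype=float),
                                  mass=mass, grid_size=grid_size)
        q_neg = qform(hdr_neg.cell_centers())
        c_limit = float(q_neg.min())
        diagnostics["n_neg"] = int(len(ck_neg))
        diagnostics["c_limit"] = c_limit
        if c_limit <= c:
            c_new = c_limit * (1.0 - 1e-9)
            coverage = float(np.mean(qform(pos_centers) < c_new))
            diagnostics["hdr_coverage_after_shrink"] = coverage
            if coverage < coverage_floor:
                overlap = float(np.mean(qform(pos_centers) >= c_new))
                raise GateInfeasibleError(
                    "CK+ and CK- main populations are inseparable: shrinking "
                    f"to exclude the CK- HDR keeps only {coverage:.1%} of the "
                    f"CK+ HDR (floor {coverage_floor:.0%}); overlapping CK+ "
                    f"HDR fraction {overlap:.1%}"
                )
            c = c_new

    diagnostics["level"] = float(c)
    eigvals, eigvecs = np.linalg.eigh(sigma)
    semi_axes = tuple(float(np.sqrt(max(v, 1e-300) * c)) for v in eigvals)
    angle = float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
    return EllipseGate(center=tuple(float(v) for v in mu),
                       semi_axes=semi_axes, angle=angle,
                       provenance=diagnostics)


# ---------------------------------------------------------------------------
# End-to-end Ki67 positivity


@dataclass(frozen=True)
class GateSet:
    """Fitted gate parameters for one sample pair.

    All cutoffs derive from the pair's control member only.
    """

    dna: DnaGate
    ck_cutoff: PercentileCutoff | None = None
    ki67_cutoff: PercentileCutoff | None = None
    areax: EllipseGate | None = None

    def to_dict(self) -> dict:
        d = {"dna": {"peak_2n": self.dna.peak_2n,
                     "window_fraction": self.dna.window_fraction}}
        for name, cut in (("ck_cutoff", self.ck_cutoff),
                          ("ki67_cutoff", self.ki67_cutoff)):
            if cut is not None:
                d[name] = {"role": cut.role, "q": cut.q, "threshold": cut.threshold}
        if self.areax is not None:
            d["areax"] = self.areax.to_dict()
        return d


@dataclass(frozen=True)
class Ki67Result:
    """Positivity plus the per-stage event counts that produced it."""

    positivity: float
    scheme: str
    gates: GateSet
    stage_counts: dict
    qc: QcRates


def ki67_positivity(pair: SamplePair, scheme: str = "areax",
                    gates: GateSet | None = None,
                    window_fraction: float = 0.2, q: float = 95.0,
                    areax: EllipseGate | None = None,
                    mass: float = 0.40) -> Ki67Result:
    """Compute Ki67 positivity for a stained/control pair under a scheme.

    Schemes: ``dapi_only`` (DNA analysis gate only), ``ck`` (plus CK
    percentile gate), ``areax`` (plus the FSC-SSC ellipse, fitted here from
    this pair's CK classification when not supplied).  The Ki67 cutoff is
    always the control's q-th percentile under the same gate chain as the
    stained events.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")

    if gates is not None and gates.dna is not None:
        dna_gate = gates.dna
    else:
        dna_gate = DnaGate(find_2n_peak(pair.stained),
                           window_fraction=window_fraction)
    part_st = dna_partition(pair.stained, dna_gate)
    part_ct = dna_partition(pair.control, dna_gate)
    qc = qc_rates(part_st)
    mask_st = part_st.analysis
    mask_ct = part_ct.analysis
    counts = {
        "total": pair.stained.n_events,
        "dna_gate": int(mask_st.sum()),
    }

    ck_cutoff = None
    if scheme == "ck":
        ck_cutoff = percentile_cutoff(pair.control, "CK", q=q, mask=mask_ct)
        mask_st = mask_st & (pair.stained.channel("CK") > ck_cutoff.threshold)
        mask_ct = mask_ct & (pair.control.channel("CK") > ck_cutoff.threshold)
        counts["ck_gate"] = int(mask_st.sum())
    elif scheme == "areax":
        ellipse = areax if areax is not None else (
            gates.areax if gates is not None else None)
        if ellipse is None:
            # per-pair refit from this pair's own CK classification
            ck_mask = ck_gate(pair, dna_gate, q=q)
            pos_pts = pair.stained.scatter()[ck_mask]
            neg_pts = pair.stained.scatter()[part_st.analysis & ~ck_mask]
            ellipse = fit_areax(pos_pts, neg_pts, mass=mass)
        in_gate_st = apply_gate(pair.stained, ellipse)
        in_gate_ct = apply_gate(pair.control, ellipse)
        mask_st = mask_st & in_gate_st
        mask_ct = mask_ct & in_gate_ct
        counts["areax_gate"] = int(mask_st.sum())
        areax = ellipse

    if not mask_st.any():
        raise ValueError(f"scheme {scheme!r}: no stained events survive the gate chain")
    ki67_cutoff = percentile_cutoff(pair.control, "KI67", q=q, mask=mask_ct)
    value = positivity(pair.stained, ki67_cutoff, mask=mask_st)
    gate_set = GateSet(dna=dna_gate, ck_cutoff=ck_cutoff,
                       ki67_cutoff=ki67_cutoff, areax=areax)
    counts["ki67_positive"] = int(
        ((pair.stained.channel("KI67") > ki67_cutoff.threshold) & mask_st).sum()
    )
    return Ki67Result(positivity=value, scheme=scheme, gates=gate_set,
                      stage_counts=counts, qc=qc)
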