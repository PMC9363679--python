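"""Layer thickness profiles and cohort statistics.

Interface paths are converted to geometric thickness by multiplying the
inter-path separation in pixels by the axial pitch (optical µm per pixel)
and dividing by the group refractive index n_G (1.387 for corneal tissue in
the near infrared).  The "epithelium" profile runs from the anterior
surface to the epithelium–Bowman's boundary and therefore includes the tear
film, whose air interface reflection dominates any tear–epithelium signal.

Also provided: the paraxial refraction correction Zr = n·Za needed to put
confocal (focus-ranged) thickness measurements on a true-depth scale, the
95% population range (mean ± 2 SD under an assumed normal distribution),
repeatability summaries, and a meta-summary of published Bowman's layer
thickness values shipped as a packaged table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .segmentation import SegmentationResult
from .synthetic import DEFAULT_N_G

__all__ = [
    "ThicknessProfile",
    "PopulationSummary",
    "RepeatabilityReport",
    "paths_to_thickness",
    "optical_to_geometric",
    "refraction_correct",
    "population_range",
    "repeatability",
    "pearson",
    "load_literature_table",
    "literature_summary",
]


@dataclass(frozen=True)
class ThicknessProfile:
    """Per-column geometric thickness (µm) of one layer.

    ``layer`` is ``"epithelium"`` (which includes the tear film by
    definition) or ``"bowman"``.
    """

    columns: np.ndarray
    thickness_um: np.ndarray
    layer: str
    n_g: float

    def __post_init__(self) -> None:
        if np.any(self.thickness_um < 0):
            raise ValueError("thickness must be non-negative")

    @property
    def mean_um(self) -> float:
        return float(self.thickness_um.mean())

    @property
    def sd_um(self) -> float:
        return float(self.thickness_um.std(ddof=1))


def paths_to_thickness(
    result: SegmentationResult, axial_pitch: float, n_g: float = DEFAULT_N_G
) -> tuple[ThicknessProfile, ThicknessProfile]:
    """Convert the three interface paths to (epithelium+tear film, Bowman's)
    geometric thickness profiles: (depth₂ − depth₁)·pitch/n_G per column."""
    if n_g <= 1:
        raise ValueError("group refractive index must exceed 1")
    z0 = result.surface.depth_index
    z1 = result.epi_bowman.depth_index
    z2 = result.bowman_stroma.depth_index
    if np.any(z1 <= z0) or np.any(z2 <= z1):
        raise ValueError("interface paths cross: cannot form thicknesses")
    cols = np.arange(z0.size)
    epi = (z1 - z0) * axial_pitch / n_g
    bow = (z2 - z1) * axial_pitch / n_g
    return (
        ThicknessProfile(columns=cols, thickness_um=epi, layer="epithelium", n_g=n_g),
        ThicknessProfile(columns=cols, thickness_um=bow, layer="bowman", n_g=n_g),
    )


def optical_to_geometric(value_um, n_g: float = DEFAULT_N_G):
    """Optical path length (n_G·µm) → geometric µm: value / n_G."""
    if n_g <= 0:
        raise ValueError("refractive index must be positive")
    return np.asarray(value_um, dtype=float) / n_g if np.ndim(value_um) else value_um / n_g


def refraction_correct(apparent_um: float, n_phase: float = 1.376) -> float:
    """Paraxial normal-interface correction Zr = n·Za for focus-ranged
    (confocal) axial measurements, whose apparent depth scale omits the
    refraction of the marginal rays at the surface."""
    if n_phase < 1:
        raise ValueError("phase refractive index must be ≥ 1")
    return n_phase * apparent_um


@dataclass(frozen=True)
class PopulationSummary:
    """Cohort mean, SD and the 95% population range (mean ± 2·SD)."""

    n_subjects: int
    mean: float
    sd: float

    @property
    def range95(self) -> tuple[float, float]:
        return (self.mean - 2 * self.sd, self.mean + 2 * self.sd)


def population_range(means) -> PopulationSummary:
    """95% population range from per-subject mean thicknesses (sample SD)."""
    means = np.asarray(means, dtype=float)
    if means.size < 2:
        raise ValueError("need at least 2 subjects for a population range")
    return PopulationSummary(
        n_subjects=means.size, mean=float(means.mean()), sd=float(means.std(ddof=1))
    )


@dataclass(frozen=True)
class RepeatabilityReport:
    """Spread of per-capture mean thicknesses.

    ``variant`` is ``"single-subject"`` (SD of one subject's repeated
    capture means) or ``"mean-over-subjects"`` (mean over subjects of the
    within-subject SD).
    """

    capture_means: tuple
    sd_of_means: float
    variant: str


def repeatability(capture_means, grouping=None) -> RepeatabilityReport:
    """Repeatability of the mean thickness.

    Without ``grouping``: sample SD of one subject's repeated capture
    means.  With ``grouping`` (a subject label per capture): the mean over
    subjects of the within-subject SD, computed over subjects with ≥ 2
    captures.
    """
    means = np.asarray(capture_means, dtype=float)
    if grouping is None:
        if means.size < 2:
            raise ValueError("need at least 2 repeated captures")
        return RepeatabilityReport(
            capture_means=tuple(means), sd_of_means=float(means.std(ddof=1)),
            variant="single-subject",
        )
    grouping = np.asarray(grouping)
    if grouping.size != means.size:
        raise ValueError("grouping must label every capture")
    sds = []
    for g in np.unique(grouping):
        vals = means[grouping == g]
        if vals.size >= 2:
            sds.append(vals.std(ddof=1))
    if not sds:
        raise ValueError("no subject has 2 or more captures")
    return RepeatabilityReport(
        capture_means=tuple(means), sd_of_means=float(np.mean(sds)),
        variant="mean-over-subjects",
    )


def pearson(x, y, exclude=None) -> float:
    """Sample Pearson correlation, honouring per-point exclusion flags
    (e.g. the contact-lens wearer in a cohort)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    from scipy.stats import pearsonr

    return float(pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# Literature meta-summary
# ---------------------------------------------------------------------------

def load_literature_table() -> pd.DataFrame:
    """The packaged table of published healthy Bowman's layer thickness
    values (mean ± SD or range, µm, plus reported repeatability)."""
    with resources.files("octcornea.data").joinpath("bowman_literature.csv").open() as fh:
        return pd.read_csv(fh)


def literature_summary(
    table: pd.DataFrame | None = None, include_this_study: bool = False
) -> tuple[float, tuple[float, float]]:
    """Meta-summary of published values: (mean of means, mean range).

    Rows contribute their printed mean, or the midpoint of their printed
    range if only a range is given; repeatability-only rows are skipped.
    The mean range averages per-row bounds, each row's bounds being
    mean ± 2·SD or its printed range.  The consensus over *prior* studies
    excludes the this-study row unless ``include_this_study`` is set.
    """
    if table is None:
        table = load_literature_table()
    rows = table
    if not include_this_study and "this_study" in rows:
        rows = rows[~rows["this_study"].astype(bool)]
    means, los, his = [], [], []
    for _, r in rows.iterrows():
        has_mean = pd.notna(r.get("mean_um"))
        has_range = pd.notna(r.get("range_lo_um")) and pd.notna(r.get("range_hi_um"))
        if has_mean and pd.notna(r.get("sd_um")):
            means.append(float(r["mean_um"]))
            los.append(float(r["mean_um"]) - 2 * float(r["sd_um"]))
            his.append(float(r["mean_um"]) + 2 * float(r["sd_um"]))
        elif has_range:
            lo, hi = float(r["range_lo_um"]), float(r["range_hi_um"])
            means.append((lo + hi) / 2)
            los.append(lo)
            his.append(hi)
        elif has_mean:
            means.append(float(r["mean_um"]))
    if not means:
        raise ValueError("no rows with a mean or range")
    mean_of_means = float(np.mean(means))
    mean_range = (float(np.mean(los)), float(np.mean(his)))
    return mean_of_means, mean_range
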