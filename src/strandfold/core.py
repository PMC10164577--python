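"""Shared domain containers.

Small validated dataclasses used across the analysis modules. Arrays are
plain numpy; tracks use 0-based half-open bins (bin ``i`` covers
``[i*w, (i+1)*w)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_ROLES = ("nicked", "supercoiled", "loading_control")
_DNA = set("ACGT")


@dataclass(frozen=True)
class PlasmidReference:
    """A reference sequence with its experimental role.

    ``role`` distinguishes the nicked plasmid (clamp-loading competent), the
    supercoiled competitor, and the linear loading-control amplicon.
    """

    name: str
    sequence: str
    circular: bool
    role: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        if not set(self.sequence) <= _DNA:
            raise ValueError(f"reference {self.name!r}: alphabet must be ACGT")
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {VALID_ROLES}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReferenceSet:
    """The three references of a nucleosome-assembly sequencing experiment."""

    references: tuple[PlasmidReference, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.references]
        if len(set(names)) != len(names):
            raise ValueError("reference names must be unique")
        roles = sorted(r.role for r in self.references)
        if roles != sorted(VALID_ROLES):
            raise ValueError("need exactly one reference per role (nicked, supercoiled, loading_control)")

    def by_role(self, role: str) -> PlasmidReference:
        for r in self.references:
            if r.role == role:
                return r
        raise KeyError(role)

    def by_name(self, name: str) -> PlasmidReference:
        for r in self.references:
            if r.name == name:
                return r
        raise KeyError(name)

    def __iter__(self):
        return iter(self.references)


@dataclass(frozen=True)
class ReadPair:
    """A simulated paired read; the ``true_*`` fields carry generator truth."""

    name: str
    r1: str
    r2: str
    true_ref: str | None = None
    true_start: int | None = None
    true_length: int | None = None


@dataclass
class StrandedBinTrack:
    """Per-bin forward/reverse signal on one reference at fixed bin width."""

    reference: str
    bin_width: int
    F: np.ndarray
    R: np.ndarray
    units: str = "counts"

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.F.shape != self.R.shape or self.F.ndim != 1:
            raise ValueError("F and R must be 1-D arrays of equal length")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if np.any(self.F < 0) or np.any(self.R < 0):
            raise ValueError("strand signals must be nonnegative")
        if self.units not in ("counts", "CPM"):
            raise ValueError("units must be 'counts' or 'CPM'")

    @property
    def n_bins(self) -> int:
        return self.F.size


@dataclass
class PartitionTrack:
    """Per-bin partition (or RFD) score in [-1, 1]; invalid bins are NaN."""

    reference: str
    bin_width: int
    value: np.ndarray
    mask: np.ndarray  # True where the score is defined

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.value.shape != self.mask.shape:
            raise ValueError("value and mask must have the same shape")
        ok = self.value[self.mask]
        if ok.size and (np.nanmax(np.abs(ok)) > 1 + 1e-12):
            raise ValueError("partition values must lie in [-1, 1]")


@dataclass(frozen=True)
class InitiationZone:
    """A replication initiation zone located by an RFD sign change."""

    reference: str
    center_bin: int
    strand_orientation: int = 1  # +1 or -1

    def __post_init__(self) -> None:
        if self.strand_orientation not in (1, -1):
            raise ValueError("strand_orientation must be +1 or -1")


@dataclass(frozen=True)
class Fragment:
    """A mapped sequenced insert; ``end`` may exceed the reference length
    when the fragment wraps the circular origin (end - start is the true
    fragment length)."""

    reference: str
    start: int
    end: int
    unique: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start after wrap resolution")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LaneProfile:
    """1-D migration profile of a single gel lane.

    ``position`` increases with migration distance (small products run far).
    Ladder annotations are optional and used by calibration.
    """

    position: np.ndarray
    intensity: np.ndarray
    lane_length: float
    ladder_positions: np.ndarray | None = None
    ladder_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position.shape != self.intensity.shape:
            raise ValueError("position and intensity must match in shape")
        if np.any(np.diff(self.position) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.lane_length <= 0:
            raise ValueError("lane_length must be positive")


@dataclass(frozen=True)
class LadderCalibration:
    """log10(size_bp) = slope * Rf + intercept, with Rf = position / lane_length."""

    slope: float
    intercept: float
    lane_length: float
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("calibration slope must be negative (large fragments migrate less)")


@dataclass(frozen=True)
class RateEstimate:
    """Maximum replication rate from a linear fit of product-front size vs time."""

    rate_kb_per_min: float
    intercept_kb: float
    n_points: int
    residual_kb_rms: float


@dataclass
class TitrationCurve:
    """Paired (concentration, response) observations from a titration."""

    concentration: np.ndarray
    response: np.ndarray
    response_kind: str = "percent_bound"  # or "polarization"

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration.shape != self.response.shape:
            raise ValueError("concentration and response must match in length")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be nonnegative")

    def __len__(self) -> int:
        return self.concentration.size


@dataclass(frozen=True)
class BindingFit:
    """Fitted one-site binding parameters and diagnostics."""

    kd: float
    hill: float
    amplitude: float
    baseline: float
    rss: float
    converged: bool

    def model(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return hill_response(c, self.kd, self.hill, self.amplitude, self.baseline)


def hill_response(
    c: np.ndarray | float, kd: float, hill: float, amplitude: float, baseline: float
) -> np.ndarray | float:
    """One-site binding with Hill slope: baseline + amplitude * c^h / (Kd^h + c^h)."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(c > 0, c**hill / (kd**hill + c**hill), 0.0)
    return baseline + amplitude * frac


@dataclass(frozen=True)
class MassPeakSet:
    """Gaussian-mixture fit of a mass-photometry histogram (shared sigma)."""

    means_kda: tuple[float, ...]
    weights: tuple[float, ...]
    sigma_kda: float

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")
        if any(w < 0 for w in self.weights) or any(m <= 0 for m in self.means_kda):
            raise ValueError("weights must be >= 0 and means positive")


@dataclass(frozen=True)
class CompositionModel:
    """Masses (kDa) used to assign mass-photometry peaks to a CAF-1 / PCNA-trimer
    stoichiometry n x CAF-1 + m x PCNA3."""

    m_caf1: float = 190.0
    m_pcna3: float = 90.0
    max_caf1: int = 3
    max_pcna3: int = 1

    def __post_init__(self) -> None:
        if self.m_caf1 <= 0 or self.m_pcna3 <= 0:
            raise ValueError("component masses must be positive")
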