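"""qPCR absolute quantification, detection limits and survival-decay fits.

The quantification model relates the initial number of gene templates per
PCR tube, N, to the quantification cycle Cq:

    N = N_T / (2 e)^Cq

where ``N_T`` is the number of amplicons per tube needed for signal
detection and ``e`` the amplification efficiency (e = 1 is perfect
doubling). Calibration is linear least squares of log N on Cq. Template
counts convert to genome counts through the rRNA-operon copy number
(3 copies of the 16S gene per genome in the inoculant strain) and to
per-gram / per-millilitre abundances through the sample mass represented in
the tube. Inoculant survival is a first-order decay N_t = N_0 exp(-d t),
with half-life T_1/2 = ln(2)/d, fitted on log abundance; the laboratory
series is piecewise (a fast phase over days ~3-7, a slow phase after), with
user-specified windows.

Calibrations are carried at full precision throughout; rounded two-digit
parameters are never substituted internally (the rounding alone shifts the
Cq-40 detection threshold from ~34 to ~46 templates per tube).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "QpcrCalibration", "QpcrSample", "DecayFit", "CopyEstimate", "Abundance",
    "fit_calibration", "copies_from_cq", "cq_from_copies", "abundance",
    "lod", "inhibition_check", "fit_decay",
]

DEFAULT_CQ_LIMIT = 40.0
DEFAULT_COPIES_PER_GENOME = 3


@dataclass
class QpcrCalibration:
    n_t: float                       # amplicons/tube at detection
    e: float                         # amplification efficiency, (0, 1]
    r_squared: float = float("nan")
    se_log_n_t: float = float("nan")
    se_e: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_t <= 0:
            raise ValueError("n_t must be positive")
        if not 0.0 < self.e <= 1.0:
            raise ValueError("efficiency e must be in (0, 1]")


@dataclass
class QpcrSample:
    sample_id: str
    cq: float
    mass_loaded_g: float             # soil-g (or digestate-ml) represented in tube
    dilution: float = 1.0            # extract dilution factor (metadata; >= 1)
    copies_per_genome: int = DEFAULT_COPIES_PER_GENOME

    def __post_init__(self) -> None:
        if self.cq < 0:
            raise ValueError("cq must be >= 0")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.mass_loaded_g <= 0:
            raise ValueError("mass_loaded_g must be positive")


@dataclass
class CopyEstimate:
    copies: float
    below_lod: bool = False


@dataclass
class Abundance:
    templates_per_g: float
    genomes_per_g: float
    below_lod: bool = False


@dataclass
class DecayFit:
    n_0: float                       # abundance at window start reference t=0
    d: float                         # day-1
    se_d: float
    window_days: tuple
    n_points: int

    @property
    def t_half_days(self) -> float:
        return float(np.log(2.0) / self.d)


# ---------------------------------------------------------------------------
# calibration and Cq conversion
# ---------------------------------------------------------------------------

def fit_calibration(known_copies, cq) -> QpcrCalibration:
    """Fit (N_T, e) from standards by regression of log N on Cq.

    log N = log N_T - Cq log(2e), so the slope gives the efficiency and the
    intercept the detection threshold. Requires >= 4 standards spanning at
    least 3 decades; non-monotone standards only warn.
    """
    n = np.asarray(known_copies, dtype=float)
    q = np.asarray(cq, dtype=float)
    if n.size < 4 or n.size != q.size:
        raise ValueError("need >= 4 matched (copies, cq) standards")
    if np.any(n <= 0):
        raise ValueError("standard copy numbers must be positive")
    if np.log10(n.max() / n.min()) < 3.0:
        raise ValueError("standards must span at least 3 decades")
    order = np.argsort(n)
    if np.any(np.diff(q[order]) > 0):
        warnings.warn("standards are not monotone in Cq; fitting all points",
                      stacklevel=2)
    res = stats.linregress(q, np.log(n))
    e = float(np.exp(-res.slope) / 2.0)
    n_t = float(np.exp(res.intercept))
    return QpcrCalibration(
        n_t=n_t, e=min(e, 1.0),
        r_squared=res.rvalue**2,
        se_log_n_t=res.intercept_stderr,
        se_e=abs(res.stderr * e),    # delta method on e = exp(-slope)/2
    )


def copies_from_cq(cq: float, cal: QpcrCalibration,
                   cq_limit: float = DEFAULT_CQ_LIMIT) -> CopyEstimate:
    """Templates per tube: N = N_T / (2e)^Cq; flags Cq above the trust limit."""
    copies = cal.n_t / (2.0 * cal.e) ** cq
    return CopyEstimate(copies=float(copies), below_lod=bool(cq > cq_limit))


def cq_from_copies(copies: float, cal: QpcrCalibration) -> float:
    """Closed-form inverse of the quantification model."""
    if copies <= 0:
        raise ValueError("copies must be positive")
    return float(np.log(cal.n_t / copies) / np.log(2.0 * cal.e))


def abundance(sample: QpcrSample, cal: QpcrCalibration,
              cq_limit: float = DEFAULT_CQ_LIMIT) -> Abundance:
    """Templates and genomes per gram (or per ml) of sample material.

    ``mass_loaded_g`` is the soil-mass (or digestate-volume) equivalent whose
    DNA is actually in the tube, i.e. with the extract dilution already
    applied; the dilution factor itself is carried as metadata.
    """
    est = copies_from_cq(sample.cq, cal, cq_limit=cq_limit)
    templates_per_g = est.copies / sample.mass_loaded_g
    return Abundance(
        templates_per_g=templates_per_g,
        genomes_per_g=templates_per_g / sample.copies_per_genome,
        below_lod=est.below_lod,
    )


@dataclass
class DetectionLimit:
    threshold_copies_per_tube: float
    templates_per_g: float
    genomes_per_g: float


def lod(cal: QpcrCalibration, cq_limit: float = DEFAULT_CQ_LIMIT,
        mass_loaded_g: float = 8e-4,
        copies_per_genome: int = DEFAULT_COPIES_PER_GENOME) -> DetectionLimit:
    """Detection limit implied by the trusted Cq ceiling and tube loading.

    Default loading is 0.8 mg soil per tube (0.2 g extracted, eluted to
    50 ul, 1/10 diluted, 2 ul per tube).
    """
    thr = copies_from_cq(cq_limit, cal, cq_limit=cq_limit).copies
    per_g = thr / mass_loaded_g
    return DetectionLimit(threshold_copies_per_tube=thr,
                          templates_per_g=per_g,
                          genomes_per_g=per_g / copies_per_genome)


# ---------------------------------------------------------------------------
# inhibition screening
# ---------------------------------------------------------------------------

@dataclass
class InhibitionResult:
    dilution_factors: np.ndarray
    delta_cq: np.ndarray             # measured - predicted, cycles
    passes: np.ndarray
    min_safe_dilution: float | None  # smallest factor with it and all larger OK
    uninterpretable: bool = False


def inhibition_check(dilution_factors, measured_cq, spike_copies_undiluted: float,
                     cal: QpcrCalibration, delta_cq_max: float = 1.0
                     ) -> InhibitionResult:
    """Screen a dilution series of a spiked extract for polymerase inhibition.

    ``dilution_factors`` are >= 1 (1 = undiluted, 10 = 1/10, ...); the
    expected template count per tube at factor D is spike/D, so the expected
    Cq follows from the calibration. Dilutions whose Cq offset exceeds
    ``delta_cq_max`` (inclusive boundary passes) are flagged inhibited; the
    minimum safe dilution is the smallest factor from which all further
    dilutions pass.
    """
    d = np.asarray(dilution_factors, dtype=float)
    m = np.asarray(measured_cq, dtype=float)
    if d.size < 3 or d.size != m.size:
        raise ValueError("need >= 3 matched (dilution, cq) points")
    order = np.argsort(d)
    d, m = d[order], m[order]
    predicted = np.array([cq_from_copies(spike_copies_undiluted / dd, cal)
                          for dd in d])
    delta = m - predicted
    passes = delta <= delta_cq_max
    min_safe = None
    for i in range(d.size):
        if passes[i:].all():
            min_safe = float(d[i])
            break
    return InhibitionResult(dilution_factors=d, delta_cq=delta, passes=passes,
                            min_safe_dilution=min_safe,
                            uninterpretable=min_safe is None)


# ---------------------------------------------------------------------------
# survival decay
# ---------------------------------------------------------------------------

def fit_decay(days, abundances, window_days: tuple | None = None) -> DecayFit:
    """First-order decay fit N_t = N_0 exp(-d t) on log abundance vs time.

    Points outside ``window_days`` (closed interval) and non-positive
    abundances (excluded with a warning) are dropped. Call once per window
    for piecewise series.
    """
    t = np.asarray(days, dtype=float)
    n = np.asarray(abundances, dtype=float)
    if t.size != n.size:
        raise ValueError("days and abundances must match")
    if window_days is not None:
        keep = (t >= window_days[0]) & (t <= window_days[1])
        t, n = t[keep], n[keep]
    pos = n > 0
    if not pos.all():
        warnings.warn(f"excluding {int((~pos).sum())} non-positive abundances",
                      stacklevel=2)
        t, n = t[pos], n[pos]
    if t.size < 3:
        raise ValueError("need >= 3 positive points in the window")
    res = stats.linregress(t, np.log(n))
    d = -res.slope
    if d <= 0:
        warnings.warn("no net decline in window: d <= 0, t_half undefined",
                      stacklevel=2)
    return DecayFit(n_0=float(np.exp(res.intercept)), d=float(d),
                    se_d=float(res.stderr),
                    window_days=(float(t[0]), float(t[-1])),
                    n_points=int(t.size))
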