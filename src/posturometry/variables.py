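"""Registry of the 18 screening endpoints.

The screening protocol yields 18 scalar endpoints per subject-session,
grouped into three sections:

* posture (quiet double-leg stance): head lateral / frontal offsets,
  neck angle, pelvic offset, height loss, weight distribution;
* balance (double stance and single-leg stance left/right): convex-hull
  sway area and 95th-percentile sway velocity per horizontal axis;
* side-bending: minimal fingertip height as % body height per side, and
  the maximal leftward weight shift.

Each endpoint carries its unit, its task of origin, and the default
generative parameters used by the synthetic cohort model (population
mean, between-subject SD, within-subject between-occasion SD, and the
low/high-fidelity device transforms).  The between/within split is
parameterised so that the expected test-retest intraclass correlation
sigma_b^2 / (sigma_b^2 + sigma_w^2) is known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "VariableSpec",
    "VARIABLES",
    "VARIABLE_NAMES",
    "SECTIONS",
    "variable",
]


@dataclass(frozen=True)
class VariableSpec:
    """Static description of one screening endpoint."""

    name: str
    section: str           # posture | balance | side_bend
    task: str              # stand | single_left | single_right | side_bend
    unit: str
    mean: float            # population mean, low-fidelity device scale
    sigma_between: float   # between-subject SD of the latent trait
    sigma_within: float    # between-occasion SD (biological + protocol)
    ref_scale: float = 1.0     # reference device reads scale*latent + offset
    ref_offset: float = 0.0

    @property
    def true_icc(self) -> float:
        b2, w2 = self.sigma_between**2, self.sigma_within**2
        if b2 + w2 == 0.0:
            return 1.0
        return b2 / (b2 + w2)


def _split(total_sd: float, icc: float) -> tuple[float, float]:
    """Split a total SD into (between, within) components for a target ICC."""
    icc = min(max(icc, 0.0), 1.0)
    return total_sd * icc**0.5, total_sd * (1.0 - icc)**0.5


# IQR of a normal is 1.349 SD; the defaults below convert observed cohort
# interquartile ranges into SDs under the generator's Gaussian components.
_IQR_TO_SD = 1.0 / 1.349


def _v(name, section, task, unit, median, iqr, icc, ref_scale=1.0, ref_offset=0.0):
    sb, sw = _split(iqr * _IQR_TO_SD, icc)
    return VariableSpec(name, section, task, unit, median, sb, sw,
                        ref_scale, ref_offset)


# Endpoint population model: medians/IQRs typical of a healthy working-age
# cohort measured with a consumer depth-camera system; between/within split
# chosen so the default cohort reproduces the reliability structure such a
# system shows (good side-bending repeatability, poor short-trial balance
# repeatability).  Printed-ICC floors: a variance ratio cannot be negative,
# so nominally negative reliabilities enter as 0.05.
# Reference-device transforms: a force plate sampling at 100 Hz registers
# roughly five-fold higher maximal CoP velocities than the 30 Hz contour
# system, and optical side-bend depth reads about 6 %height higher.
VARIABLES: tuple[VariableSpec, ...] = (
    _v("P-HL", "posture", "stand", "cm", 1.34, 2.42, 0.329),
    _v("P-HF", "posture", "stand", "cm", 2.28, 6.52, 0.326),
    _v("P-NA", "posture", "stand", "deg", -2.85, 6.26, 0.723),
    _v("P-PP", "posture", "stand", "cm", 0.45, 1.13, 0.308),
    _v("P-HS", "posture", "stand", "cm", 0.33, 0.32, 0.655),
    _v("P-WB", "posture", "stand", "% left leg", 48.52, 7.00, 0.231),
    _v("DS-SA", "balance", "stand", "cm^2", 0.10, 0.10, 0.125),
    _v("DS-SVAP", "balance", "stand", "cm/s", 0.70, 0.50, 0.013, ref_scale=5.0),
    _v("DS-SVML", "balance", "stand", "cm/s", 0.30, 0.15, 0.013, ref_scale=5.0),
    _v("SSL-SA", "balance", "single_left", "cm^2", 0.50, 0.70, 0.177),
    _v("SSL-SVAP", "balance", "single_left", "cm/s", 1.20, 0.85, 0.228, ref_scale=5.0),
    _v("SSL-SVML", "balance", "single_left", "cm/s", 1.40, 1.30, 0.162, ref_scale=5.0),
    _v("SSR-SA", "balance", "single_right", "cm^2", 0.50, 0.70, 0.05),
    _v("SSR-SVAP", "balance", "single_right", "cm/s", 1.20, 0.75, 0.048, ref_scale=5.0),
    _v("SSR-SVML", "balance", "single_right", "cm/s", 1.40, 1.00, 0.05, ref_scale=5.0),
    _v("SB-LF", "side_bend", "side_bend", "% body height", 29.93, 3.09, 0.898,
       ref_offset=6.0),
    _v("SB-RF", "side_bend", "side_bend", "% body height", 29.77, 3.33, 0.394,
       ref_offset=6.0),
    _v("SB-%BW", "side_bend", "side_bend", "%", 85.01, 14.15, 0.693),
)

VARIABLE_NAMES: tuple[str, ...] = tuple(v.name for v in VARIABLES)

SECTIONS = ("posture", "balance", "side_bend")

_BY_NAME = {v.name: v for v in VARIABLES}


def variable(name: str) -> VariableSpec:
    """Look up one endpoint by its abbreviation (e.g. ``"SB-LF"``)."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown endpoint {name!r}; known: {VARIABLE_NAMES}") from None
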