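"""Inhalation unit risk (IUR) computation and comparison utilities.

The IUR is the benchmark response divided by the human-equivalent point of
departure: IUR = BMR / POD, expressed per ppm and per µg/m³.  Optional
age-dependent adjustment factor (ADAF) machinery is provided for
comparison with assessments that assume a mutagenic mode of action; the
default pipeline applies no ADAF.
"""

from __future__ import annotations

from dataclasses import dataclass

from .conversion import PPM_TO_UGM3, ppm_to_ugm3

__all__ = [
    "IURResult",
    "compute_iur",
    "potency_ratio",
    "apply_adaf",
    "rounded_summary",
    "round_sig",
    "EPA_ADAF_WINDOWS",
]

#: EPA default early-life susceptibility windows over a 70-year lifetime:
#: 10-fold for ages 0-2, 3-fold for ages 2-16, none thereafter.
EPA_ADAF_WINDOWS = ((2.0 / 70.0, 10.0), (14.0 / 70.0, 3.0), (54.0 / 70.0, 1.0))


@dataclass(frozen=True)
class IURResult:
    bmr: float
    pod_ppm: float
    pod_ugm3: float
    iur_per_ppm: float
    iur_per_ugm3: float
    adaf_applied: bool = False
    adaf_factor: float = 1.0


def compute_iur(
    bmr: float, pod_ppm: float, ppm_to_ugm3_constant: float = PPM_TO_UGM3
) -> IURResult:
    """IUR = BMR / POD in per-ppm and per-µg/m³ forms."""
    if not 0 < bmr < 1:
        raise ValueError("bmr must lie in (0, 1)")
    if pod_ppm <= 0:
        raise ValueError("pod_ppm must be > 0")
    pod_ugm3 = ppm_to_ugm3(pod_ppm, ppm_to_ugm3_constant)
    return IURResult(
        bmr=bmr,
        pod_ppm=pod_ppm,
        pod_ugm3=pod_ugm3,
        iur_per_ppm=bmr / pod_ppm,
        iur_per_ugm3=bmr / pod_ugm3,
    )


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures."""
    return float(f"{x:.{sig}g}")


def rounded_summary(
    bmdl: float,
    bmr: float = 0.01,
    factor: float = 0.0106,
    ppm_constant: float = PPM_TO_UGM3,
) -> dict[str, float]:
    """Display-rounded conversion chain from an internal-dose BMDL.

    Mirrors summary-table practice, rounding at each step: the
    human-equivalent concentration to 3 significant figures in ppm, its
    µg/m³ form to the nearest integer, the per-ppm unit risk to 3
    significant figures, and the per-µg/m³ unit risk to 2.  Each quantity
    is derived from the previously *rounded* one, so the chain reproduces
    published rows digit for digit; full-precision values come from
    :func:`compute_iur`.
    """
    pod_ppm = round_sig(bmdl / factor, 3)
    pod_ugm3 = float(round(pod_ppm * ppm_constant))
    return {
        "pod_ppm": pod_ppm,
        "pod_ugm3": pod_ugm3,
        "iur_per_ppm": round_sig(bmr / pod_ppm, 3),
        "iur_per_ugm3": round_sig(bmr / pod_ugm3, 2),
    }


def potency_ratio(reference_iur: float, new_iur: float) -> float:
    """How many times lower the new unit risk is than the reference.

    Both unit risks must be on the same scale (e.g. both per µg/m³).
    """
    if reference_iur <= 0 or new_iur <= 0:
        raise ValueError("unit risks must be > 0")
    return reference_iur / new_iur


def apply_adaf(
    iur: IURResult, weights: tuple[tuple[float, float], ...] = EPA_ADAF_WINDOWS
) -> IURResult:
    """Scale a unit risk by lifetime-weighted age-dependent adjustment factors.

    ``weights`` is a sequence of (age-window fraction of lifetime, factor)
    pairs; fractions must sum to 1 and factors be >= 1.
    """
    fractions = [w for w, _ in weights]
    factors = [f for _, f in weights]
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"age-window fractions must sum to 1, got {sum(fractions)}")
    if any(f < 1 for f in factors):
        raise ValueError("ADAF factors must be >= 1")
    scale = sum(w * f for w, f in weights)
    return IURResult(
        bmr=iur.bmr,
        pod_ppm=iur.pod_ppm,
        pod_ugm3=iur.pod_ugm3,
        iur_per_ppm=iur.iur_per_ppm * scale,
        iur_per_ugm3=iur.iur_per_ugm3 * scale,
        adaf_applied=True,
        adaf_factor=scale,
    )
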