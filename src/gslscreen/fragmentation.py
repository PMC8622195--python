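"""Negative-mode glycosidic fragment prediction and MS/MS subclass scoring.

Acidic glycosphingolipids fragment in negative mode predominantly at
glycosidic bonds, yielding B-type oxocarbenium-derived anions from the
non-reducing (sialylated) end and Y-type ions that retain the ceramide.
O-acetylated sialic acids shift the sialo-B ions by +42.011 Da per acetyl
group, which is the diagnostic signature that separates, e.g., GT1b-Ac2
from GT1b: the non-acetylated subclass cannot explain the +42/+84-shifted
sialo fragments.  Scoring a spectrum against candidate species on (i) the
fraction of diagnostic ions observed, (ii) matched fragment count and
(iii) matched intensity fraction reproduces that assignment logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .library import MONOMERS, PROTON_MASS, IonSpecies, LipidSpecies

__all__ = [
    "MsmsSpectrum",
    "FragmentIon",
    "SpectrumScore",
    "predict_fragments",
    "diagnostic_fragments",
    "score_spectrum",
    "rank_candidates",
]

_NEUAC = MONOMERS["NeuAc"].residue_mass
_OAC = MONOMERS["OAc"].residue_mass


@dataclass
class MsmsSpectrum:
    """A centroided MS/MS spectrum with known precursor charge state."""

    precursor_mz: float
    precursor_charge: int
    peaks: np.ndarray  # (n, 2) array of (mz, intensity), sorted by mz

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if len(self.peaks):
            if np.any(self.peaks[:, 1] <= 0):
                raise ValueError("peak intensities must be positive")
            self.peaks = self.peaks[np.argsort(self.peaks[:, 0], kind="stable")]

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]


@dataclass(frozen=True)
class FragmentIon:
    kind: str  # "B", "Y", or "NL" (precursor neutral loss)
    label: str
    charge: int
    theo_mz: float
    retains_ceramide: bool
    diagnostic: bool = False


def predict_fragments(species: LipidSpecies, precursor_charge: int) -> list[FragmentIon]:
    """Enumerate glycosidic fragment ions for a candidate species.

    Emitted series (duplicates removed):

    * B-type sialo fragments: k NeuAc (k = 1..sialic count) carrying a = 0..
      (acetyl count) O-acetyl groups, singly deprotonated;
    * Y-type ions: precursor minus 1..k terminal NeuAc (with optional OAc)
      losses, at charges 1..precursor_charge;
    * precursor minus k*NeuAc neutral losses at the precursor charge.

    Cross-ring cleavages and ceramide-internal fragmentation are outside
    the subclass-assignment scope and are not predicted.
    """
    if sum(species.headgroup.counts.values()) < 1:
        raise ValueError("species has no glycan residues to fragment")
    n_sia = species.headgroup.n_sialic
    n_oac = species.headgroup.counts.get("OAc", 0)
    neutral = species.neutral_mass

    frags: list[FragmentIon] = []
    seen: set[tuple[int, int]] = set()

    def _add(frag: FragmentIon) -> None:
        key = (frag.charge, int(round(frag.theo_mz * 1e5)))
        if frag.theo_mz > 0 and key not in seen:
            seen.add(key)
            frags.append(frag)

    # B-type sialo ions (ceramide-free, hence identical across a subclass)
    for k in range(1, n_sia + 1):
        for a in range(0, n_oac + 1):
            mz = k * _NEUAC + a * _OAC - PROTON_MASS
            label = f"B{k}" + (f"+{a}OAc" if a else "")
            _add(FragmentIon("B", label, 1, mz, False, diagnostic=True))

    # Y-type: losses of terminal sialic acids (optionally acetylated)
    for k in range(1, n_sia + 1):
        for a in range(0, n_oac + 1):
            loss = k * _NEUAC + a * _OAC
            for z in range(1, precursor_charge + 1):
                mz = (neutral - loss - z * PROTON_MASS) / z
                label = f"Y-{k}NeuAc" + (f"-{a}OAc" if a else "") + f"^{z}-"
                diagnostic = k == 1 and a == 0 and z == precursor_charge
                _add(FragmentIon("Y", label, z, mz, True, diagnostic=diagnostic))

    # precursor - k*NeuAc neutral losses at the precursor charge
    for k in range(1, n_sia + 1):
        z = precursor_charge
        mz = (neutral - k * _NEUAC - z * PROTON_MASS) / z
        _add(FragmentIon("NL", f"[M-{k}NeuAc-{z}H]^{z}-", z, mz, True))

    frags.sort(key=lambda f: (f.theo_mz, f.charge))
    return frags


def diagnostic_fragments(species: LipidSpecies, precursor_charge: int) -> list[FragmentIon]:
    """Sialo-B ions plus the first NeuAc loss at the precursor charge."""
    return [f for f in predict_fragments(species, precursor_charge) if f.diagnostic]


@dataclass
class SpectrumScore:
    """Deterministic match summary of a spectrum against one candidate."""

    candidate: LipidSpecies
    n_predicted: int
    n_matched: int
    diagnostic_fraction: float
    matched_intensity_fraction: float
    precursor_ppm: float

    @property
    def matched_fraction(self) -> float:
        return self.n_matched / self.n_predicted if self.n_predicted else 0.0

    @property
    def composite(self) -> float:
        """Scalar score: diagnostic evidence first, then coverage, then intensity."""
        return (
            0.6 * self.diagnostic_fraction
            + 0.3 * self.matched_fraction
            + 0.1 * self.matched_intensity_fraction
        )

    def sort_key(self) -> tuple:
        return (
            -self.diagnostic_fraction,
            -self.n_matched,
            -self.matched_intensity_fraction,
            abs(self.precursor_ppm) if np.isfinite(self.precursor_ppm) else np.inf,
        )


def _match_mask(peak_mz: np.ndarray, targets: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Boolean per target: any observed peak within tol_ppm."""
    if len(peak_mz) == 0 or len(targets) == 0:
        return np.zeros(len(targets), dtype=bool)
    idx = np.searchsorted(peak_mz, targets)
    best = np.full(len(targets), np.inf)
    for off in (-1, 0):
        j = np.clip(idx + off, 0, len(peak_mz) - 1)
        best = np.minimum(best, np.abs(peak_mz[j] - targets))
    return best <= targets * tol_ppm * 1e-6


def score_spectrum(
    spectrum: MsmsSpectrum, candidate: LipidSpecies, tol_ppm: float = 20.0
) -> SpectrumScore:
    """Score an observed spectrum against one candidate species.

    Returns matched-fragment count, fraction of diagnostic ions observed,
    and the fraction of total peak intensity explained by predicted
    fragments.  MS/MS centroids are matched in a ppm window (default 20
    ppm, wider than the MS1 threshold).
    """
    if len(spectrum.peaks) == 0:
        raise ValueError("spectrum has no peaks")
    try:
        frags = predict_fragments(candidate, spectrum.precursor_charge)
    except ValueError:
        frags = []
    if not frags:
        return SpectrumScore(candidate, 0, 0, 0.0, 0.0, float("nan"))

    targets = np.array([f.theo_mz for f in frags])
    matched = _match_mask(spectrum.mz, targets, tol_ppm)
    diag = np.array([f.diagnostic for f in frags])
    diag_frac = float(matched[diag].mean()) if diag.any() else 0.0

    # intensity explained: peaks within tol of any matched prediction
    peak_matched = np.zeros(len(spectrum.mz), dtype=bool)
    for t in targets[matched]:
        peak_matched |= np.abs(spectrum.mz - t) <= spectrum.mz * tol_ppm * 1e-6
    int_frac = float(spectrum.intensity[peak_matched].sum() / spectrum.intensity.sum())

    theo_prec = IonSpecies(candidate, spectrum.precursor_charge).theo_mz
    prec_ppm = 1e6 * (spectrum.precursor_mz - theo_prec) / theo_prec
    return SpectrumScore(candidate, len(frags), int(matched.sum()), diag_frac, int_frac, prec_ppm)


def rank_candidates(
    spectrum: MsmsSpectrum,
    candidates: Sequence[LipidSpecies],
    tol_ppm: float = 20.0,
) -> list[SpectrumScore]:
    """Order candidate species by spectrum support.

    Stable sort on (diagnostic fraction, matched count, matched intensity
    fraction), ties broken by smaller absolute precursor ppm error, then by
    shorthand so the ordering is independent of input order.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    scores = [score_spectrum(spectrum, c, tol_ppm) for c in candidates]
    scores.sort(key=lambda s: s.sort_key() + (s.candidate.shorthand,))
    return scores
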