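"""Probe-site localization among positional isomers of an accepted PSM.

For a peptide with several target residues (cysteines, for the bundled
probe), the probe can a priori sit on any of them.  Each positional isomer is
scored by the binomial match-probability of its own fragment set — the only
ions that differ between isomers are the site-determining ones, i.e.
fragments that span one candidate site but not the other — and the isomer
scores are normalized into probabilities with a base-10 softmax, the
PTM-score convention.  Peptides whose best probability falls below 0.75 are
classified ambiguous: counted toward totals and intensities but excluded
from site-specific analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import ModifiedPeptide, ProbeDefinition
from .search import PSM, SearchParams, score_psm
from .spectra import Ms2Spectrum

__all__ = ["SiteLocalization", "localize", "classify_site",
           "LOCALIZATION_THRESHOLD"]

#: Best-probability threshold below which a site is ambiguous; exactly at the
#: threshold counts as localized (ambiguity is defined strictly below it).
LOCALIZATION_THRESHOLD = 0.75


@dataclass(frozen=True)
class SiteLocalization:
    psm: PSM
    candidate_positions: tuple[int, ...]
    probabilities: tuple[float, ...]
    best_position: int
    best_probability: float

    def __post_init__(self):
        total = sum(self.probabilities)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"isomer probabilities sum to {total}, not 1")
        if not np.isclose(self.best_probability, max(self.probabilities)):
            raise ValueError("best_probability is not the maximum")


def _isomer(candidate: ModifiedPeptide, probe_name: str,
            position: int) -> ModifiedPeptide:
    mods = tuple((position if name == probe_name else pos, name, delta)
                 for pos, name, delta in candidate.modifications)
    return ModifiedPeptide(sequence=candidate.sequence, modifications=mods,
                           protein_refs=candidate.protein_refs,
                           missed_cleavages=candidate.missed_cleavages)


def localize(
    psm: PSM,
    spectrum: Ms2Spectrum,
    probe: ProbeDefinition,
    tol_ppm: float = 20.0,
) -> SiteLocalization:
    """Localization probabilities over the positional isomers of one PSM.

    The PSM must carry exactly one probe modification.  A peptide with a
    single target residue localizes there with probability 1; when no
    site-determining ions are matched all isomers score equally and the
    probabilities are uniform.
    """
    probe_mods = [(pos, name, delta) for pos, name, delta in
                  psm.candidate.modifications if name == probe.name]
    if len(probe_mods) != 1:
        raise ValueError(
            f"localization needs exactly one probe modification, found "
            f"{len(probe_mods)}")
    occupied = {pos for pos, name, _d in psm.candidate.modifications
                if name != probe.name}
    positions = tuple(
        i for i, aa in enumerate(psm.candidate.sequence, start=1)
        if aa == probe.target_residue and i not in occupied
    )
    if not positions:
        raise ValueError("peptide has no available target residue")

    # Isomers are scored on backbone fragments with the intact adduct only:
    # a fragment minus the full-adduct loss is mass-identical to its
    # unmodified form, so neutral-loss variants (and the sequence-independent
    # diagnostic ions) carry no positional information and are excluded.
    params = SearchParams(fragment_tol_ppm=tol_ppm, use_probe_evidence=False)
    scores = np.array([
        score_psm(spectrum, _isomer(psm.candidate, probe.name, pos),
                  probe, params).score
        for pos in positions
    ])
    # base-10 softmax of the -log10 p scores (PTM-score convention)
    shifted = scores - scores.max()
    weights = np.power(10.0, shifted)
    probs = weights / weights.sum()
    best = int(np.argmax(probs))
    return SiteLocalization(
        psm=psm,
        candidate_positions=positions,
        probabilities=tuple(float(p) for p in probs),
        best_position=positions[best],
        best_probability=float(probs[best]),
    )


def classify_site(localization: SiteLocalization,
                  threshold: float = LOCALIZATION_THRESHOLD) -> str:
    """``"localized"`` iff the best probability reaches the threshold
    (inclusive), else ``"ambiguous"``."""
    return ("localized" if localization.best_probability >= threshold
            else "ambiguous")
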