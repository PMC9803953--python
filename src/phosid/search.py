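"""Probe-adduct-aware spectrum matching with target-decoy FDR control.

Candidates are digested peptides and their variable-modification forms,
indexed by neutral mass.  Each spectrum is matched against all candidates
within the precursor tolerance; the score is a binomial-model -log10 match
probability over matched versus possible fragment ions.  When probe evidence
is enabled, fragment variants carrying the adduct's neutral losses and the
adduct's diagnostic ions join the candidate ion set — but only for candidates
that actually carry the probe, so unlabeled candidates cannot absorb probe
evidence.  Confidence is controlled by the classical target-decoy q-value at
the PSM level, with a protein-level pass on best-peptide evidence.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import (ModifiedPeptide, ProbeDefinition, TheoreticalFragment,
                   fragment_ions, peptide_mass)
from .proteolysis import (DigestParams, ProteinEntry, VariableModification,
                          apply_variable_modifications, digest_nonspecific,
                          digest_tryptic)
from .spectra import Ms2Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SearchParams",
    "PSM",
    "make_decoys",
    "build_candidate_index",
    "CandidateIndex",
    "match_peaks",
    "detect_diagnostic_ions",
    "score_psm",
    "search_run",
    "psm_table",
    "DECOY_PREFIX",
]

DECOY_PREFIX = "REV_"


@dataclass(frozen=True)
class SearchParams:
    """Search tolerances and filters.

    Defaults mirror the tryptic regime: 4.5 ppm precursor and 20 ppm fragment
    tolerance, 1% PSM and protein FDR.  ``min_score_modified`` is an extra
    score floor applied to modified PSMs; its default of 5.0 sits at roughly
    the upper tail of decoy-match scores of this binomial scorer on small
    synthetic databases (search-engine score scales are not comparable across
    engines, so no published cutoff value is claimed).
    """

    precursor_tol_ppm: float = 4.5
    fragment_tol_ppm: float = 20.0
    fdr_psm: float = 0.01
    fdr_protein: float = 0.01
    min_score_modified: float = 5.0
    use_probe_evidence: bool = True
    max_fragment_charge: int = 2

    def __post_init__(self):
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        for f in (self.fdr_psm, self.fdr_protein):
            if not 0 < f <= 1:
                raise ValueError("FDR must be in (0, 1]")


@dataclass(frozen=True)
class PSM:
    """A scored peptide-spectrum match."""

    scan_id: str
    candidate: ModifiedPeptide
    score: float
    matched_peak_annotations: tuple[tuple[int, str], ...]
    diagnostic_evidence: tuple[tuple[float, float, float, float], ...]
    is_decoy: bool
    precursor_charge: int
    q_value: float = float("nan")

    @property
    def has_probe(self) -> bool:
        return any("probe" in name or "phosphonate" in name
                   for _p, name, _d in self.candidate.modifications)


def make_decoys(proteins: Sequence[ProteinEntry]) -> list[ProteinEntry]:
    """One decoy per target by full sequence reversal, id prefixed."""
    if not proteins:
        raise ValueError("empty protein database")
    decoys = []
    for p in proteins:
        rev = p.sequence[::-1]
        if rev == p.sequence:
            logger.info("palindromic sequence: decoy equals target for %s",
                        p.id)
        decoys.append(ProteinEntry(id=DECOY_PREFIX + p.id,
                                   description=p.description,
                                   sequence=rev))
    return decoys


@dataclass
class CandidateIndex:
    """Mass-sorted candidate peptides (targets and decoys together)."""

    masses: np.ndarray
    candidates: list[ModifiedPeptide]

    def lookup(self, neutral_mass: float, tol_ppm: float
               ) -> list[ModifiedPeptide]:
        tol = neutral_mass * tol_ppm * 1e-6
        lo = bisect.bisect_left(self.masses, neutral_mass - tol)
        hi = bisect.bisect_right(self.masses, neutral_mass + tol)
        return self.candidates[lo:hi]


def default_modifications(probe: ProbeDefinition) -> list[VariableModification]:
    """The variable-modification set of the tryptic search regime."""
    from .chem import MODIFICATION_DELTAS as D
    return [
        VariableModification("carbamidomethyl", D["carbamidomethyl"], "C"),
        VariableModification("oxidation", D["oxidation"], "M"),
        VariableModification(probe.name, probe.adduct_mass,
                             probe.target_residue),
    ]


def build_candidate_index(
    proteins: Sequence[ProteinEntry],
    probe: ProbeDefinition,
    digest_params: DigestParams = DigestParams(),
    modifications: Sequence[VariableModification] | None = None,
    max_mods_per_peptide: int = 2,
    with_decoys: bool = True,
) -> CandidateIndex:
    """Digest targets (and reversed decoys), expand modification forms, and
    index every form by neutral mass."""
    if modifications is None:
        modifications = default_modifications(probe)
    pool = list(proteins) + (make_decoys(proteins) if with_decoys else [])
    digest = (digest_tryptic if digest_params.mode == "tryptic"
              else digest_nonspecific)
    entries: list[tuple[float, ModifiedPeptide]] = []
    seen: set[tuple[str, tuple, bool]] = set()
    for protein in pool:
        for peptide in digest(protein, digest_params):
            for form in apply_variable_modifications(
                    peptide, modifications, max_mods_per_peptide):
                key = (form.sequence, form.modifications,
                       protein.id.startswith(DECOY_PREFIX))
                if key in seen:
                    continue
                seen.add(key)
                entries.append((peptide_mass(form), form))
    entries.sort(key=lambda t: t[0])
    return CandidateIndex(
        masses=np.array([m for m, _ in entries]),
        candidates=[c for _, c in entries],
    )


def _is_decoy(candidate: ModifiedPeptide) -> bool:
    return all(pid.startswith(DECOY_PREFIX)
               for pid, _s in candidate.protein_refs)


def match_peaks(
    spectrum: Ms2Spectrum,
    fragments: Sequence[TheoreticalFragment],
    tol_ppm: float,
) -> list[tuple[int, str]]:
    """Match theoretical ions to observed peaks, nearest-by-ppm.

    Each theoretical ion matches at most one peak; each observed peak is used
    at most once per annotation class (the ion series, or ``diagnostic``).
    When two peaks are equidistant in ppm the lower-m/z peak wins.
    """
    mz = spectrum.peaks_mz
    out: list[tuple[int, str]] = []
    used: dict[str, set[int]] = {}
    for frag in fragments:
        tol = frag.mz * tol_ppm * 1e-6
        lo = np.searchsorted(mz, frag.mz - tol, side="left")
        hi = np.searchsorted(mz, frag.mz + tol, side="right")
        if lo >= hi:
            continue
        cls = frag.series
        taken = used.setdefault(cls, set())
        best = None
        best_err = None
        for idx in range(lo, hi):
            if idx in taken:
                continue
            err = abs(mz[idx] - frag.mz)
            if best is None or err < best_err - 1e-12:
                best, best_err = idx, err
            # ties: the lower-m/z peak (first seen) is kept
        if best is None:
            continue
        taken.add(best)
        label = f"{frag.series}{frag.index}"
        if frag.charge > 1:
            label += f"({frag.charge}+)"
        if frag.loss:
            label += f"-{frag.loss}"
        out.append((int(best), label))
    return out


def detect_diagnostic_ions(
    spectrum: Ms2Spectrum,
    probe: ProbeDefinition,
    tol_ppm: float = 20.0,
) -> list[tuple[float, float, float, float]]:
    """Diagnostic ions present in the spectrum.

    Returns ``(theoretical_mz, observed_mz, intensity, ppm_error)`` for every
    diagnostic ion of the probe with a peak within tolerance.
    """
    if not probe.diagnostic_ions:
        raise ValueError("probe has an empty diagnostic-ion table")
    mz = spectrum.peaks_mz
    inten = spectrum.peaks_intensity
    out = []
    for ion in probe.diagnostic_ions:
        tol = ion * tol_ppm * 1e-6
        lo = np.searchsorted(mz, ion - tol, side="left")
        hi = np.searchsorted(mz, ion + tol, side="right")
        if lo >= hi:
            continue
        idx = lo + int(np.argmin(np.abs(mz[lo:hi] - ion)))
        out.append((ion, float(mz[idx]), float(inten[idx]),
                    (mz[idx] - ion) / ion * 1e6))
    return out


def _candidate_fragments(
    candidate: ModifiedPeptide,
    probe: ProbeDefinition,
    params: SearchParams,
) -> tuple[list[TheoreticalFragment], int]:
    """Fragment set for scoring and the number of scorable ions.

    NL variants ride along automatically inside :func:`fragment_ions` for
    probe-carrying candidates; diagnostic ions are appended as a pseudo-series
    when probe evidence is on and the candidate carries the probe.
    """
    carries_probe = any(name == probe.name
                        for _p, name, _d in candidate.modifications)
    frags = fragment_ions(
        candidate, series=("b", "y"),
        max_charge=params.max_fragment_charge,
        probe=probe if (params.use_probe_evidence and carries_probe) else None,
    )
    if params.use_probe_evidence and carries_probe:
        for ion in probe.diagnostic_ions:
            frags.append(TheoreticalFragment("diagnostic", 0, 1, "", ion))
    return frags, len(frags)


def score_psm(
    spectrum: Ms2Spectrum,
    candidate: ModifiedPeptide,
    probe: ProbeDefinition,
    params: SearchParams = SearchParams(),
) -> PSM:
    """Binomial-model -log10 match-probability score.

    With ``k`` of ``N`` candidate ions matched and a per-ion chance match
    probability ``p`` estimated from spectrum peak density and the fragment
    tolerance, the score is ``-log10 P[Binom(N, p) >= k]``: zero when nothing
    matches and strictly increasing as matched annotations accumulate.
    """
    frags, n_possible = _candidate_fragments(candidate, probe, params)
    annotations = match_peaks(spectrum, frags, params.fragment_tol_ppm)
    # Diagnostic ions are sequence-independent: every probe-carrying
    # candidate in the precursor window shares them, so they only count on
    # top of at least one backbone (sequence-specific) fragment match.
    if not any(not label.startswith("diagnostic")
               for _i, label in annotations):
        annotations = []
    k = len(annotations)
    score = 0.0
    if k > 0 and n_possible > 0:
        mz = spectrum.peaks_mz
        span = float(mz[-1] - mz[0]) if mz.size > 1 else 1000.0
        span = max(span, 100.0)
        mean_mz = float(mz.mean()) if mz.size else 500.0
        window = 2.0 * params.fragment_tol_ppm * 1e-6 * mean_mz
        p = min(0.5, max(1e-6, spectrum.n_peaks * window / span))
        # survival at k-1 gives P[X >= k]
        sf = stats.binom.sf(k - 1, n_possible, p)
        score = float(-np.log10(max(sf, 1e-300)))
    carries_probe = any(name == probe.name
                        for _p, name, _d in candidate.modifications)
    evidence = (tuple(detect_diagnostic_ions(
        spectrum, probe, params.fragment_tol_ppm))
        if (params.use_probe_evidence and carries_probe) else ())
    return PSM(
        scan_id=spectrum.scan_id,
        candidate=candidate,
        score=score,
        matched_peak_annotations=tuple(annotations),
        diagnostic_evidence=evidence,
        is_decoy=_is_decoy(candidate),
        precursor_charge=spectrum.precursor_charge,
    )


def _neutral_mass(spectrum: Ms2Spectrum, carrier: float) -> float:
    z = spectrum.precursor_charge
    return spectrum.precursor_mz * z - z * carrier


def _assign_q_values(psms: list[PSM]) -> list[PSM]:
    """Target-decoy q-values at descending score (decoys / targets,
    monotonized from the bottom)."""
    order = sorted(range(len(psms)), key=lambda i: -psms[i].score)
    n_decoy = 0
    n_target = 0
    fdrs = []
    for i in order:
        if psms[i].is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        fdrs.append(n_decoy / max(n_target, 1))
    # q-value: minimum FDR at this threshold or any more permissive one
    q = np.minimum.accumulate(np.array(fdrs)[::-1])[::-1]
    out = list(psms)
    for rank, i in enumerate(order):
        out[i] = replace(psms[i], q_value=float(q[rank]))
    return out


def search_run(
    spectra: Sequence[Ms2Spectrum],
    proteins: Sequence[ProteinEntry] | CandidateIndex,
    probe: ProbeDefinition,
    digest_params: DigestParams = DigestParams(),
    modifications: Sequence[VariableModification] | None = None,
    params: SearchParams = SearchParams(),
) -> list[PSM]:
    """Search a run and return accepted target PSMs (q-valued, filtered).

    The best-scoring candidate per spectrum is retained (targets and decoys
    compete); q-values come from decoy counting at descending score; accepted
    PSMs satisfy ``q <= fdr_psm``, modified PSMs additionally
    ``score >= min_score_modified``; finally proteins failing the
    protein-level FDR (computed on best-peptide evidence) are removed.
    Ties between equal-scoring candidates break toward fewer modifications,
    then lexicographically smaller sequence.
    """
    if isinstance(proteins, CandidateIndex):
        index = proteins
    else:
        if not proteins:
            logger.warning("empty protein database: no PSMs")
            return []
        index = build_candidate_index(proteins, probe, digest_params,
                                      modifications)
    if not spectra:
        logger.warning("empty spectrum set: no PSMs")
        return []

    best_per_scan: list[PSM] = []
    for spectrum in spectra:
        mass = _neutral_mass(spectrum, probe.charge_carrier_mass)
        candidates = index.lookup(mass, params.precursor_tol_ppm)
        best: PSM | None = None
        for candidate in candidates:
            psm = score_psm(spectrum, candidate, probe, params)
            if best is None:
                best = psm
                continue
            key = (-psm.score, psm.candidate.n_modifications,
                   psm.candidate.sequence)
            best_key = (-best.score, best.candidate.n_modifications,
                        best.candidate.sequence)
            if key < best_key:
                best = psm
        if best is not None and best.score > 0:
            best_per_scan.append(best)

    qvalued = _assign_q_values(best_per_scan)
    accepted = [
        p for p in qvalued
        if not p.is_decoy and p.q_value <= params.fdr_psm
        and (p.candidate.n_modifications == 0
             or p.score >= params.min_score_modified)
    ]

    # protein-level FDR on best-peptide evidence over all scored PSMs
    best_protein: dict[str, tuple[float, bool]] = {}
    for p in qvalued:
        for pid, _s in p.candidate.protein_refs:
            prev = best_protein.get(pid)
            if prev is None or p.score > prev[0]:
                best_protein[pid] = (p.score, p.is_decoy)
    rows = sorted(best_protein.items(), key=lambda kv: -kv[1][0])
    n_d = n_t = 0
    passing: set[str] = set()
    fdr_rows = []
    for pid, (score, is_decoy) in rows:
        if is_decoy:
            n_d += 1
        else:
            n_t += 1
        fdr_rows.append((pid, is_decoy, n_d / max(n_t, 1)))
    qs = np.minimum.accumulate(
        np.array([f for _p, _d, f in fdr_rows])[::-1])[::-1]
    for (pid, is_decoy, _f), q in zip(fdr_rows, qs):
        if not is_decoy and q <= params.fdr_protein:
            passing.add(pid)
    accepted = [
        p for p in accepted
        if any(pid in passing for pid, _s in p.candidate.protein_refs)
    ]
    return sorted(accepted, key=lambda p: (-p.score, p.scan_id))


def psm_table(psms: Sequence[PSM]) -> pd.DataFrame:
    """Tab-separable PSM table: one row per accepted PSM."""
    rows = []
    for p in psms:
        rows.append({
            "scan": p.scan_id,
            "sequence": p.candidate.sequence,
            "modifications": ";".join(
                f"{name}@{pos}" for pos, name, _d in
                p.candidate.modifications),
            "charge": p.precursor_charge,
            "score": p.score,
            "q_value": p.q_value,
            "n_matched_ions": len(p.matched_peak_annotations),
            "diagnostic_ions_matched": ";".join(
                f"{theo:.5f}" for theo, _o, _i, _e in p.diagnostic_evidence),
            "proteins": ";".join(pid for pid, _s in
                                 p.candidate.protein_refs),
        })
    return pd.DataFrame(rows)
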