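"""Seeded synthetic fixtures: proteomes, spectra, ground truth.

Everything downstream is testable offline against runs generated here.  The
generator emulates the statistical structure the method assumes rather than
biological realism: random proteomes with a configurable cysteine frequency,
probe-labeled peptides as a small roster fraction, fragment spectra with
planted b/y ions, probe neutral-loss variants and diagnostic ions, uniform
chemical noise, and the extreme abundance skew of an enrichment workflow
(labeled peptides carrying ~1e-5..1e-3 of total intensity before enrichment
and ~0.2-0.3 after).

All randomness flows through one ``numpy`` Generator seeded per run;
sub-seeds for pipeline stages are derived deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (HYDROGEN_MASS, ModifiedPeptide, ProbeDefinition,
                   fragment_ions, peptide_mass)
from .proteolysis import DigestParams, ProteinEntry, digest_tryptic
from .spectra import Ms2Spectrum

__all__ = [
    "make_proteome",
    "synthesize_spectrum",
    "BENCHMARK_DIGEST",
    "make_search_benchmark",
    "realized_fdp",
    "plant_labels",
    "site_intensity_matrix",
    "make_enrichment_intensities",
]

# Residue background approximating vertebrate proteome composition, with the
# cysteine share kept separate so labelable-site density is configurable.
_BACKGROUND = {
    "A": 0.074, "D": 0.053, "E": 0.063, "F": 0.038, "G": 0.071,
    "H": 0.026, "I": 0.052, "K": 0.058, "L": 0.095, "M": 0.021,
    "N": 0.043, "P": 0.050, "Q": 0.042, "R": 0.052, "S": 0.081,
    "T": 0.056, "V": 0.063, "W": 0.012, "Y": 0.032,
}


def make_proteome(
    n_proteins: int,
    mean_length: int = 240,
    cys_freq: float = 0.025,
    seed: int = 0,
    id_prefix: str = "SYN",
) -> list[ProteinEntry]:
    """Random protein entries with approximately the configured residue
    frequencies; reproducible for a fixed seed."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    letters = list(_BACKGROUND) + ["C"]
    base = np.array(list(_BACKGROUND.values()))
    probs = np.concatenate([base / base.sum() * (1.0 - cys_freq), [cys_freq]])
    entries = []
    for i in range(n_proteins):
        length = max(30, int(rng.normal(mean_length, mean_length / 6)))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        entries.append(ProteinEntry(
            id=f"{id_prefix}{i + 1:04d}",
            description=f"synthetic protein {i + 1}",
            sequence=seq,
        ))
    return entries


def synthesize_spectrum(
    peptide: ModifiedPeptide,
    probe: ProbeDefinition,
    rng: np.random.Generator,
    scan_id: str,
    charge: int = 2,
    nce: float = 28.0,
    retention_time: float = 0.0,
    frag_detect_prob: float = 0.7,
    nl_yield: float = 0.6,
    di_yield: float = 0.85,
    noise_peaks: float = 25.0,
    base_intensity: float = 1e5,
    provenance: str = "survey",
    trigger_parent_scan: str | None = None,
) -> Ms2Spectrum:
    """A centroided MS2 spectrum with planted fragment evidence.

    Singly charged b/y ions appear independently with ``frag_detect_prob``;
    for probe-carrying peptides, neutral-loss variants appear with
    ``nl_yield`` and each diagnostic ion with ``di_yield`` (diagnostic ions
    are intense, as observed in practice).  Chemical noise is Poisson many
    uniform peaks at low exponential intensity.  Deterministic given the
    passed Generator state.
    """
    carries_probe = any(name == probe.name
                        for _p, name, _d in peptide.modifications)
    frags = fragment_ions(peptide, series=("b", "y"), max_charge=1,
                          probe=probe if carries_probe else None)
    mz_list: list[float] = []
    int_list: list[float] = []
    for frag in frags:
        prob = frag_detect_prob if not frag.loss else nl_yield
        if rng.random() < prob:
            mz_list.append(frag.mz)
            int_list.append(base_intensity * rng.lognormal(0.0, 0.6))
    if carries_probe:
        for ion in probe.diagnostic_ions:
            if rng.random() < di_yield:
                mz_list.append(ion)
                int_list.append(3.0 * base_intensity * rng.lognormal(0.0, 0.4))
    n_noise = rng.poisson(noise_peaks)
    if n_noise:
        mz_list.extend(rng.uniform(120.0, 1700.0, size=n_noise))
        int_list.extend(0.05 * base_intensity
                        * rng.exponential(1.0, size=n_noise))
    mass = peptide_mass(peptide)
    precursor_mz = (mass + charge * probe.charge_carrier_mass) / charge
    return Ms2Spectrum(
        scan_id=scan_id,
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        retention_time=retention_time,
        peaks_mz=np.array(mz_list),
        peaks_intensity=np.array(int_list),
        nce=nce,
        provenance=provenance,
        trigger_parent_scan=trigger_parent_scan,
    )


#: Digestion used by the bundled search benchmark: tryptic, one missed
#: cleavage, lengths 6..25 — small enough for desk-scale candidate indexes.
BENCHMARK_DIGEST = DigestParams(mode="tryptic", max_missed_cleavages=1,
                                min_length=6, max_length=25)


def _unique_peptides(proteome, digest_params) -> list[ModifiedPeptide]:
    seen: set[str] = set()
    out = []
    for protein in proteome:
        for pep in digest_tryptic(protein, digest_params):
            if pep.sequence not in seen:
                seen.add(pep.sequence)
                out.append(pep)
    return out


def make_search_benchmark(
    proteome: list[ProteinEntry],
    probe: ProbeDefinition,
    n_spectra: int = 200,
    labeled_fraction: float = 0.3,
    foreign_fraction: float = 0.3,
    seed: int = 0,
    digest_params: DigestParams = BENCHMARK_DIGEST,
    frag_detect_prob: float = 0.7,
    labeled_frag_detect_prob: float | None = None,
    nl_yield: float = 0.6,
    di_yield: float = 0.85,
    noise_peaks: float = 25.0,
) -> tuple[list[Ms2Spectrum], pd.DataFrame]:
    """A seeded run of spectra with per-spectrum ground truth.

    ``labeled_fraction`` of the in-database spectra come from probe-labeled
    cysteine peptides; ``foreign_fraction`` of all spectra come from peptides
    of a disjoint random proteome absent from the search database, so false
    matches are possible and realized FDR is measurable.
    ``labeled_frag_detect_prob`` lets labeled peptides fragment worse than
    unlabeled ones (the bulky adduct suppresses backbone fragmentation at a
    fixed collision energy); it defaults to the common value.
    """
    rng = np.random.default_rng(seed)
    peptides = _unique_peptides(proteome, digest_params)
    cys_peptides = [p for p in peptides if probe.target_residue in p.sequence]
    if not peptides or not cys_peptides:
        raise ValueError("proteome yields no (cysteine) peptides to sample")

    foreign_proteome = make_proteome(
        max(4, len(proteome) // 4), seed=int(rng.integers(2 ** 31)),
        id_prefix="FOREIGN")
    foreign_db = {p.sequence for p in peptides}
    foreign_peptides = [p for p in _unique_peptides(foreign_proteome,
                                                    digest_params)
                        if p.sequence not in foreign_db]

    n_foreign = int(round(n_spectra * foreign_fraction))
    n_true = n_spectra - n_foreign
    n_labeled = int(round(n_true * labeled_fraction))

    spectra: list[Ms2Spectrum] = []
    truth_rows = []
    scan = 0

    lab_prob = (labeled_frag_detect_prob if labeled_frag_detect_prob
                is not None else frag_detect_prob)

    def emit(peptide: ModifiedPeptide, labeled: bool, foreign: bool):
        nonlocal scan
        scan += 1
        charge = int(rng.choice([2, 3], p=[0.7, 0.3]))
        s = synthesize_spectrum(
            peptide, probe, rng, scan_id=f"S{scan:05d}", charge=charge,
            retention_time=float(rng.uniform(0, 3600)),
            frag_detect_prob=lab_prob if labeled else frag_detect_prob,
            nl_yield=nl_yield,
            di_yield=di_yield, noise_peaks=noise_peaks)
        spectra.append(s)
        truth_rows.append({
            "scan": s.scan_id,
            "sequence": peptide.sequence,
            "modifications": ";".join(
                f"{n}@{p}" for p, n, _d in peptide.modifications),
            "labeled": labeled,
            "foreign": foreign,
        })

    labeled_pool = rng.choice(len(cys_peptides),
                              size=min(n_labeled, len(cys_peptides)),
                              replace=False)
    for idx in labeled_pool:
        base = cys_peptides[int(idx)]
        sites = [i for i, aa in enumerate(base.sequence, start=1)
                 if aa == probe.target_residue]
        pos = int(rng.choice(sites))
        labeled = ModifiedPeptide(
            sequence=base.sequence,
            modifications=((pos, probe.name, probe.adduct_mass),),
            protein_refs=base.protein_refs,
            missed_cleavages=base.missed_cleavages)
        emit(labeled, labeled=True, foreign=False)
    for _ in range(n_true - len(labeled_pool)):
        emit(peptides[int(rng.integers(len(peptides)))],
             labeled=False, foreign=False)
    for _ in range(n_foreign):
        emit(foreign_peptides[int(rng.integers(len(foreign_peptides)))],
             labeled=False, foreign=True)

    return spectra, pd.DataFrame(truth_rows)


def realized_fdp(accepted, truth: pd.DataFrame) -> tuple[int, int]:
    """(false, total) accepted PSMs against benchmark ground truth.

    A PSM is false when its spectrum came from a foreign peptide, or its
    sequence (or probe state) disagrees with the source peptide.
    """
    lookup = truth.set_index("scan")
    false = 0
    for psm in accepted:
        row = lookup.loc[psm.scan_id]
        probe_mods = ";".join(f"{n}@{p}" for p, n, _d in
                              psm.candidate.modifications)
        if bool(row["foreign"]):
            false += 1
        elif psm.candidate.sequence != row["sequence"]:
            false += 1
        elif probe_mods != row["modifications"]:
            false += 1
    return false, len(accepted)


# ---------------------------------------------------------------------------
# quantification-side ground truth


def plant_labels(
    proteome: list[ProteinEntry],
    site_rate: float = 0.25,
    n_replicates: int = 3,
    conditions: tuple[str, str] = ("lysate", "intact"),
    effect_fraction: float = 0.2,
    effect_log2fc: float = 2.0,
    base_log2_mean: float = 24.0,
    base_log2_sd: float = 1.5,
    replicate_sd: float = 0.4,
    missing_midpoint: float = 21.0,
    missing_steepness: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled cysteine sites with per-condition replicate intensities.

    A ``site_rate`` fraction of cysteines (on digestible tryptic peptides)
    is labeled.  ``effect_fraction`` of the labeled sites get a true
    between-condition effect of ``±effect_log2fc`` (random sign, second
    condition relative to first); the rest have none.  Replicate log2
    intensities add Gaussian noise, and low-abundance observations go
    missing with logistic probability — the missing-at-low-abundance
    mechanism the downshifted imputation targets.

    Returns one row per (site, condition, replicate) with the planted truth
    columns ``true_log2fc`` and ``intensity`` (NaN when missing).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for protein in proteome:
        for pep in digest_tryptic(protein, BENCHMARK_DIGEST):
            for offset, aa in enumerate(pep.sequence):
                if aa != "C" or rng.random() > site_rate:
                    continue
                position = pep.protein_refs[0][1] + offset
                base = rng.normal(base_log2_mean, base_log2_sd)
                if rng.random() < effect_fraction:
                    fc = effect_log2fc * (1 if rng.random() < 0.5 else -1)
                else:
                    fc = 0.0
                for ci, condition in enumerate(conditions):
                    mean = base + (fc if ci == 1 else 0.0)
                    for rep in range(1, n_replicates + 1):
                        value = rng.normal(mean, replicate_sd)
                        p_missing = 1.0 / (1.0 + np.exp(
                            missing_steepness * (value - missing_midpoint)))
                        missing = rng.random() < p_missing
                        rows.append({
                            "protein": protein.id,
                            "position": position,
                            "peptide": pep.sequence,
                            "condition": condition,
                            "replicate": rep,
                            "true_log2fc": fc,
                            "intensity": (np.nan if missing
                                          else float(2.0 ** value)),
                        })
    return pd.DataFrame(rows)


def site_intensity_matrix(truth: pd.DataFrame) -> pd.DataFrame:
    """Pivot planted ground truth to a site x (condition, replicate) log2
    matrix, the shape the quantification pipeline consumes."""
    df = truth.copy()
    df["sample"] = df["condition"] + "_" + df["replicate"].astype(str)
    wide = (df.groupby(["protein", "position", "sample"])["intensity"]
              .sum(min_count=1).unstack("sample"))
    return np.log2(wide)


def make_enrichment_intensities(
    labeled_fraction_pre: float = 1e-5,
    labeled_fraction_post: float = 0.23,
    phospho_fraction_post: float = 0.14,
    total_intensity: float = 1e12,
    n_psms: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-PSM class/intensity tables for a before/after enrichment pair.

    Pre-enrichment, probe-labeled peptides carry a vanishing share of total
    intensity; post-enrichment they dominate alongside residual
    phosphopeptides and unmodified background.  Planted class fractions are
    exact by construction (intensities are scaled to the requested shares).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for run, fractions in (
        ("input", {"probe": labeled_fraction_pre, "phospho": 0.02,
                   "unmodified": 1.0 - labeled_fraction_pre - 0.02}),
        ("elution", {"probe": labeled_fraction_post,
                     "phospho": phospho_fraction_post,
                     "unmodified": 1.0 - labeled_fraction_post
                     - phospho_fraction_post}),
    ):
        for cls, fraction in fractions.items():
            n = max(2, int(n_psms * max(fraction, 0.01)))
            raw = rng.lognormal(0.0, 1.0, size=n)
            scaled = raw / raw.sum() * fraction * total_intensity
            for value in scaled:
                rows.append({"run": run, "class": cls,
                             "intensity": float(value)})
    return pd.DataFrame(rows)
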