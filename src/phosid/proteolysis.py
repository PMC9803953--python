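"""In-silico digestion: tryptic and nonspecific (pepsin-search-style) regimes.

Two regimes mirror the two search set-ups the pipeline supports: trypsin
specificity (cleavage C-terminal to K/R except before proline, with missed
cleavages) and a nonspecific search space of all bounded-length substrings,
which is how pepsin digests are searched in practice — the enzyme's own loose
preference is deliberately not modelled.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from pyteomics import fasta as _fasta

from .chem import ModifiedPeptide, RESIDUE_MASSES

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinEntry",
    "DigestParams",
    "read_fasta",
    "write_fasta",
    "digest_tryptic",
    "digest_nonspecific",
    "VariableModification",
    "apply_variable_modifications",
    "count_theoretical_peptides",
]

_STANDARD_ALPHABET = set(RESIDUE_MASSES)


@dataclass(frozen=True)
class ProteinEntry:
    id: str
    description: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _STANDARD_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains nonstandard residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class DigestParams:
    """Digestion regime and bounds.

    Defaults follow the tryptic search settings of the workflow: up to three
    missed cleavages, minimum length 4, no upper length bound.  The
    nonspecific (pepsin-search) regime uses 6..30.
    """

    mode: str = "tryptic"                 # 'tryptic' | 'nonspecific'
    max_missed_cleavages: int = 3
    min_length: int = 4
    max_length: int | None = None

    def __post_init__(self):
        if self.mode not in ("tryptic", "nonspecific"):
            raise ValueError(f"unknown digestion mode {self.mode!r}")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.max_length is not None and self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")


PEPSIN_SEARCH_PARAMS = DigestParams(mode="nonspecific", min_length=6,
                                    max_length=30, max_missed_cleavages=0)


def read_fasta(path) -> list[ProteinEntry]:
    """Read a FASTA file; the id is the header up to the first whitespace."""
    entries = []
    with _fasta.read(str(path)) as reader:
        for description, sequence in reader:
            parts = description.split(None, 1)
            entries.append(ProteinEntry(
                id=parts[0],
                description=parts[1] if len(parts) > 1 else "",
                sequence=sequence.upper(),
            ))
    return entries


def write_fasta(entries: Iterable[ProteinEntry], path) -> None:
    records = [(f"{e.id} {e.description}".strip(), e.sequence) for e in entries]
    _fasta.write(records, str(path), file_mode="w")


def _tryptic_sites(sequence: str) -> list[int]:
    """Cleavage points as 0-based indices *after* which the chain is cut."""
    return [
        i for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest_tryptic(protein: ProteinEntry,
                   params: DigestParams = DigestParams()) -> list[ModifiedPeptide]:
    """Tryptic peptides with 0..max_missed_cleavages internal uncleaved sites.

    Cleaves C-terminal to K or R unless the next residue is proline.  Each
    peptide records its 1-based start in the parent protein and its
    missed-cleavage count; peptides outside the length bounds are dropped.
    """
    if params.mode != "tryptic":
        raise ValueError("digest_tryptic requires mode='tryptic'")
    seq = protein.sequence
    cuts = _tryptic_sites(seq)
    # segment boundaries: starts of the fully cleaved segments
    starts = [0] + [c + 1 for c in cuts]
    ends = [c + 1 for c in cuts] + [len(seq)]
    out: list[ModifiedPeptide] = []
    for i, start in enumerate(starts):
        for missed in range(params.max_missed_cleavages + 1):
            j = i + missed
            if j >= len(ends):
                break
            sub = seq[start:ends[j]]
            if len(sub) < params.min_length:
                continue
            if params.max_length is not None and len(sub) > params.max_length:
                continue
            out.append(ModifiedPeptide(
                sequence=sub,
                protein_refs=((protein.id, start + 1),),
                missed_cleavages=missed,
            ))
    return out


def digest_nonspecific(protein: ProteinEntry,
                       params: DigestParams = PEPSIN_SEARCH_PARAMS
                       ) -> list[ModifiedPeptide]:
    """Every substring with length in [min_length, max_length]."""
    if params.mode != "nonspecific":
        raise ValueError("digest_nonspecific requires mode='nonspecific'")
    seq = protein.sequence
    n = len(seq)
    max_len = params.max_length if params.max_length is not None else n
    out: list[ModifiedPeptide] = []
    for length in range(params.min_length, min(max_len, n) + 1):
        for start in range(n - length + 1):
            out.append(ModifiedPeptide(
                sequence=seq[start:start + length],
                protein_refs=((protein.id, start + 1),),
            ))
    return out


@dataclass(frozen=True)
class VariableModification:
    """A variable modification: name, exact delta and target residues.

    ``protein_nterm_only`` restricts the modification to position 1 of a
    peptide whose protein start is 1 (e.g. protein N-terminal acetylation).
    """

    name: str
    delta: float
    residues: str
    protein_nterm_only: bool = False


def apply_variable_modifications(
    peptide: ModifiedPeptide,
    modifications: Sequence[VariableModification],
    max_mods_per_peptide: int = 3,
    max_forms: int = 512,
) -> list[ModifiedPeptide]:
    """Enumerate modified forms: at most one modification per residue, at most
    ``max_mods_per_peptide`` total; the unmodified form is always included.

    If the enumeration would exceed ``max_forms`` the peptide is skipped
    entirely (empty list) with a logged warning, mirroring how search engines
    cap combinatorial explosions rather than erroring out.
    """
    site_options: list[tuple[int, list[VariableModification]]] = []
    for pos, aa in enumerate(peptide.sequence, start=1):
        applicable = []
        for mod in modifications:
            if mod.protein_nterm_only:
                at_protein_start = any(start == 1 for _pid, start in
                                       peptide.protein_refs) and pos == 1
                if not at_protein_start:
                    continue
                applicable.append(mod)
            elif aa in mod.residues:
                applicable.append(mod)
        if applicable:
            site_options.append((pos, applicable))

    # quick upper bound on the number of forms before enumerating
    bound = 1
    for _pos, opts in site_options:
        bound *= 1 + len(opts)
        if bound > max_forms:
            logger.warning(
                "skipping peptide %s: > %d modified forms",
                peptide.sequence, max_forms)
            return []

    forms: list[ModifiedPeptide] = []
    for k in range(0, min(max_mods_per_peptide, len(site_options)) + 1):
        for chosen_sites in itertools.combinations(site_options, k):
            for combo in itertools.product(*(opts for _p, opts in chosen_sites)):
                mods = tuple(
                    (pos, mod.name, mod.delta)
                    for (pos, _opts), mod in zip(chosen_sites, combo)
                )
                forms.append(ModifiedPeptide(
                    sequence=peptide.sequence,
                    modifications=mods,
                    protein_refs=peptide.protein_refs,
                    missed_cleavages=peptide.missed_cleavages,
                ))
    return forms


def count_theoretical_peptides(protein: ProteinEntry,
                               min_length: int = 7,
                               max_length: int = 30) -> int:
    """Count of length-bounded fully tryptic peptides, the iBAQ denominator."""
    params = DigestParams(mode="tryptic", max_missed_cleavages=0,
                          min_length=min_length, max_length=max_length)
    return len(digest_tryptic(protein, params))
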