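"""Elemental-formula arithmetic, peptide and fragment masses, and probe ion tables.

All mass arithmetic in the package flows through the element and residue
tables bundled as package data (``data/elements.tsv``, ``data/residues.tsv``),
so every module derives masses from one source of truth.  Residue masses are
*residue* masses (peptide-bond units, no water); a free peptide adds one water.

The probe definition bundled by default describes the PF-06672131-phosphonate
cysteine adduct (C29H34N9O6ClFP, 689.20422 Da monoisotopic).  Collisional
fragmentation of the adduct at its ether bond produces characteristic neutral
losses and low-mass diagnostic ions that appear in MS2 regardless of peptide
sequence; :func:`probe_ion_table` re-derives those constants from the adduct
mass and flags any inconsistency in a user-edited probe config.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Sequence

import yaml

__all__ = [
    "FormulaError",
    "ElementalFormula",
    "parse_formula",
    "monoisotopic_mass",
    "ModifiedPeptide",
    "peptide_mass",
    "ProbeDefinition",
    "load_probe",
    "default_probe",
    "probe_ion_table",
    "TheoreticalFragment",
    "fragment_ions",
    "gravy",
    "ELEMENT_MASSES",
    "RESIDUE_FORMULAS",
    "RESIDUE_MASSES",
    "MODIFICATION_DELTAS",
    "WATER_MASS",
    "HYDROGEN_MASS",
    "PROTON_MASS",
]


class FormulaError(ValueError):
    """Raised for malformed chemical formulas or unknown element symbols."""


def _load_elements() -> dict[str, float]:
    out: dict[str, float] = {}
    text = resources.files("phosid.data").joinpath("elements.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, mass = line.split("\t")
        out[symbol] = float(mass)
    return out


ELEMENT_MASSES: dict[str, float] = _load_elements()

HYDROGEN_MASS = ELEMENT_MASSES["H"]          # H atom; default charge carrier
PROTON_MASS = 1.00727646688                  # H atom minus the electron
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element → count map; counts are non-negative integers.

    Hashable and additive; ``str()`` gives the canonical Hill-order formula
    (C first, then H, then other elements alphabetically; alphabetical
    throughout when no carbon is present).
    """

    counts: Mapping[str, int]

    def __post_init__(self):
        clean = {}
        for symbol, count in self.counts.items():
            if symbol not in ELEMENT_MASSES:
                raise FormulaError(f"unknown element symbol: {symbol!r}")
            count = int(count)
            if count < 0:
                raise FormulaError(f"negative count for {symbol}: {count}")
            clean[symbol] = count
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for symbol, count in other.counts.items():
            merged[symbol] = merged.get(symbol, 0) + count
        return ElementalFormula(merged)

    def __str__(self) -> str:
        items = {s: c for s, c in self.counts.items() if c > 0}
        order: list[str] = []
        if "C" in items:
            order.append("C")
            if "H" in items:
                order.append("H")
            order.extend(sorted(s for s in items if s not in ("C", "H")))
        else:
            order.extend(sorted(items))
        return "".join(f"{s}{items[s] if items[s] != 1 else ''}" for s in order)


def parse_formula(text: str) -> ElementalFormula:
    """Parse ``"C29H34N9O6ClFP"``-style formulas; a bare symbol counts as 1.

    Repeated symbols accumulate.  Unknown symbols raise :class:`FormulaError`
    naming the offending symbol.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"unparseable formula near {text[pos:]!r}")
        symbol, digits = match.groups()
        if symbol not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol: {symbol!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"unparseable formula near {text[pos:]!r}")
    return ElementalFormula(counts)


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass in Da: sum of count x elemental monoisotopic mass."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(ELEMENT_MASSES[s] * c for s, c in formula.counts.items())


def _load_residues() -> dict[str, ElementalFormula]:
    out: dict[str, ElementalFormula] = {}
    text = resources.files("phosid.data").joinpath("residues.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        letter, formula = line.split("\t")
        out[letter] = parse_formula(formula)
    return out


RESIDUE_FORMULAS: dict[str, ElementalFormula] = _load_residues()
RESIDUE_MASSES: dict[str, float] = {
    aa: monoisotopic_mass(f) for aa, f in RESIDUE_FORMULAS.items()
}

WATER_MASS = monoisotopic_mass("H2O")
_CO_MASS = monoisotopic_mass("CO")

#: Exact monoisotopic deltas of the variable modifications used in the search.
MODIFICATION_DELTAS: dict[str, float] = {
    "carbamidomethyl": monoisotopic_mass("C2H3NO"),    # +57.02146
    "oxidation": monoisotopic_mass("O"),               # +15.99491
    "phospho": monoisotopic_mass("HPO3"),              # +79.96633
    "carbamyl": monoisotopic_mass("CHNO"),             # +43.00581
    "acetyl": monoisotopic_mass("C2H2O"),              # +42.01057
}

#: Kyte-Doolittle hydropathy values, used for the GRAVY index.
_KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with positioned modifications.

    ``modifications`` holds ``(position, name, delta_mass)`` tuples with
    1-based residue positions; at most one modification per position.
    ``protein_refs`` holds ``(protein_id, start)`` with a 1-based start of the
    peptide in the parent protein.
    """

    sequence: str
    modifications: tuple[tuple[int, str, float], ...] = ()
    protein_refs: tuple[tuple[str, int], ...] = ()
    missed_cleavages: int = 0

    def __post_init__(self):
        n = len(self.sequence)
        seen: set[int] = set()
        for pos, name, _delta in self.modifications:
            if not 1 <= pos <= n:
                raise ValueError(
                    f"modification {name!r} at position {pos} outside 1..{n}"
                )
            if pos in seen:
                raise ValueError(f"multiple modifications at position {pos}")
            seen.add(pos)
        object.__setattr__(self, "modifications",
                           tuple(sorted(self.modifications)))

    @property
    def n_modifications(self) -> int:
        return len(self.modifications)

    def modification_at(self, pos: int) -> tuple[str, float] | None:
        for p, name, delta in self.modifications:
            if p == pos:
                return name, delta
        return None

    def mod_string(self) -> str:
        """Compact text form, e.g. ``HGEVC[probe@5]PAGWK``-style summary."""
        if not self.modifications:
            return self.sequence
        tags = ";".join(f"{name}@{pos}" for pos, name, _ in self.modifications)
        return f"{self.sequence}[{tags}]"


def peptide_mass(peptide: ModifiedPeptide | str) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    if isinstance(peptide, str):
        peptide = ModifiedPeptide(peptide)
    if not peptide.sequence:
        raise ValueError("empty peptide sequence")
    total = WATER_MASS
    for i, aa in enumerate(peptide.sequence, start=1):
        if aa not in RESIDUE_MASSES:
            raise ValueError(f"nonstandard residue {aa!r} at position {i}")
        total += RESIDUE_MASSES[aa]
    total += sum(delta for _pos, _name, delta in peptide.modifications)
    return total


@dataclass(frozen=True)
class ProbeDefinition:
    """The adduct chemistry of an activity-based probe handle.

    ``neutral_losses`` are in Da and include the full-adduct loss; losses
    strictly smaller than the adduct mass are the ether-bond (partial)
    losses.  ``diagnostic_ions`` are singly charged m/z values; the subset in
    ``trigger_ions`` drives mass-triggered acquisition.
    """

    name: str
    adduct_formula: ElementalFormula
    adduct_mass: float
    target_residue: str
    diagnostic_ions: tuple[float, ...]
    neutral_losses: tuple[float, ...]
    trigger_ions: tuple[float, ...]
    charge_carrier_mass: float = HYDROGEN_MASS
    checked_diagnostic_ions: tuple[float, ...] = ()
    ms1_species: tuple[float, ...] = ()

    def __post_init__(self):
        derived = monoisotopic_mass(self.adduct_formula)
        if abs(derived - self.adduct_mass) > 1e-4:
            raise ValueError(
                f"adduct_mass {self.adduct_mass} differs from formula mass "
                f"{derived:.5f} by more than 1e-4 Da"
            )
        diag = set(self.diagnostic_ions)
        if not set(self.trigger_ions) <= diag:
            raise ValueError("trigger_ions must be a subset of diagnostic_ions")
        for loss in self.neutral_losses:
            if loss > self.adduct_mass + 1e-9:
                raise ValueError(
                    f"neutral loss {loss} exceeds the adduct mass "
                    f"{self.adduct_mass}"
                )
        if len(self.target_residue) != 1 or self.target_residue not in RESIDUE_MASSES:
            raise ValueError(f"invalid target residue {self.target_residue!r}")

    @property
    def ether_bond_losses(self) -> tuple[float, ...]:
        """Partial (ether-bond) losses: all losses short of the full adduct."""
        return tuple(sorted(l for l in self.neutral_losses
                            if l < self.adduct_mass - 1e-6))


def load_probe(source) -> ProbeDefinition:
    """Load a probe definition from a YAML mapping, path or file object."""
    if isinstance(source, dict):
        raw = source
    elif hasattr(source, "read"):
        raw = yaml.safe_load(source.read())
    else:
        with open(source) as handle:
            raw = yaml.safe_load(handle)
    formula = parse_formula(raw["adduct_formula"])
    return ProbeDefinition(
        name=raw["name"],
        adduct_formula=formula,
        adduct_mass=float(raw.get("adduct_mass", monoisotopic_mass(formula))),
        target_residue=raw["target_residue"],
        diagnostic_ions=tuple(float(x) for x in raw["diagnostic_ions"]),
        neutral_losses=tuple(float(x) for x in raw["neutral_losses"]),
        trigger_ions=tuple(float(x) for x in raw["trigger_ions"]),
        charge_carrier_mass=float(raw.get("charge_carrier_mass", HYDROGEN_MASS)),
        checked_diagnostic_ions=tuple(
            float(x) for x in raw.get("checked_diagnostic_ions", ())
        ),
        ms1_species=tuple(float(x) for x in raw.get("ms1_species", ())),
    )


def default_probe() -> ProbeDefinition:
    """The bundled PF-06672131-phosphonate cysteine-adduct definition."""
    text = resources.files("phosid.data").joinpath(
        "pf06672131_phosphonate.yaml").read_text()
    return load_probe(yaml.safe_load(text))


def probe_ion_table(probe: ProbeDefinition) -> dict:
    """Re-derive the probe's characteristic ions and check self-consistency.

    Fragmentation at the adduct's ether bond implies three relations:

    * intact diagnostic ion  = adduct mass + charge carrier,
    * partial diagnostic ion = adduct mass - smallest ether-bond loss
      + charge carrier,
    * paired (hydrated) loss = smallest ether-bond loss + H2O.

    Returns the derived values plus a ``discrepancies`` list naming every
    derived value that differs by more than 1e-4 Da from its declared
    counterpart (matched to the nearest declared value).  Ions declared only
    at 2-decimal precision are outside ``checked_diagnostic_ions`` and are
    not checked.
    """
    losses = probe.ether_bond_losses
    if not losses:
        raise ValueError("probe declares no ether-bond neutral losses")
    smallest = losses[0]
    derived = {
        "derived_intact_ion": probe.adduct_mass + probe.charge_carrier_mass,
        "derived_partial_ion": probe.adduct_mass - smallest
        + probe.charge_carrier_mass,
        "derived_paired_loss": smallest + WATER_MASS,
    }
    checked = probe.checked_diagnostic_ions or probe.diagnostic_ions
    declared_for = {
        "derived_intact_ion": checked,
        "derived_partial_ion": checked,
        "derived_paired_loss": probe.neutral_losses,
    }
    discrepancies = []
    for key, value in derived.items():
        pool = declared_for[key]
        nearest = min(pool, key=lambda x: abs(x - value))
        if abs(nearest - value) > 1e-4:
            discrepancies.append(
                {"ion": key, "derived": value, "nearest_declared": nearest,
                 "delta": value - nearest}
            )
    return {**derived, "discrepancies": discrepancies}


class TheoreticalFragment(NamedTuple):
    series: str          # 'a', 'b' or 'y'
    index: int           # 1-based fragment number within the series
    charge: int
    loss: str            # '' or the neutral-loss label, e.g. 'NL274.08309'
    mz: float


def _prefix_masses(peptide: ModifiedPeptide) -> list[float]:
    """Cumulative residue+modification masses of prefixes 1..n."""
    deltas = {pos: d for pos, _n, d in peptide.modifications}
    out = []
    acc = 0.0
    for i, aa in enumerate(peptide.sequence, start=1):
        if aa not in RESIDUE_MASSES:
            raise ValueError(f"nonstandard residue {aa!r} at position {i}")
        acc += RESIDUE_MASSES[aa] + deltas.get(i, 0.0)
        out.append(acc)
    return out


def fragment_ions(
    peptide: ModifiedPeptide,
    series: Iterable[str] = ("b", "y"),
    max_charge: int = 1,
    probe: ProbeDefinition | None = None,
) -> list[TheoreticalFragment]:
    """Theoretical a/b/y fragment ions with probe neutral-loss variants.

    For every base fragment that spans the probe-modified residue, one extra
    variant per probe neutral loss is emitted with that loss subtracted.
    Variants that would have non-positive mass are dropped.  m/z uses the
    probe's charge-carrier mass (hydrogen atom by default).
    """
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    series = tuple(series)
    for s in series:
        if s not in ("a", "b", "y"):
            raise ValueError(f"unknown ion series {s!r}")
    carrier = probe.charge_carrier_mass if probe else HYDROGEN_MASS
    n = len(peptide.sequence)
    prefix = _prefix_masses(peptide)
    total = prefix[-1]

    probe_positions = set()
    if probe is not None:
        probe_positions = {
            pos for pos, name, _d in peptide.modifications
            if name == probe.name or name == "probe"
        }
    losses: Sequence[float] = probe.neutral_losses if probe else ()

    out: list[TheoreticalFragment] = []

    def emit(ser: str, idx: int, neutral: float, spans_probe: bool):
        variants = [("", neutral)]
        if spans_probe:
            for loss in losses:
                if neutral - loss > 0:
                    variants.append((f"NL{loss:.5f}", neutral - loss))
        for label, mass in variants:
            for z in range(1, max_charge + 1):
                out.append(TheoreticalFragment(
                    ser, idx, z, label, (mass + z * carrier) / z))

    for i in range(1, n):                      # fragment index 1..n-1
        b_mass = prefix[i - 1]                 # N-terminal, no water
        y_mass = total - prefix[i - 1] + WATER_MASS
        spans_b = any(p <= i for p in probe_positions)
        spans_y = any(p > i for p in probe_positions)
        if "b" in series:
            emit("b", i, b_mass, spans_b)
        if "a" in series:
            emit("a", i, b_mass - _CO_MASS, spans_b)
        if "y" in series:
            emit("y", n - i, y_mass, spans_y)
    return out


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        return sum(_KYTE_DOOLITTLE[aa] for aa in sequence) / len(sequence)
    except KeyError as exc:
        raise ValueError(f"nonstandard residue {exc.args[0]!r}") from exc
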