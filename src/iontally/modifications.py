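"""Modification registry, compilation of fixed/variable sets, residue look-ups.

A search specification names fixed and variable modifications in the Unimod
style, e.g. ``"Oxidation (M)"`` or ``"Acetyl (Protein N-term)"``.  Fixed and
variable modifications can interact in chemically unsound ways — a lysine
cannot carry both a fixed TMT label and a variable acetyl group.  The
compiler resolves such conflicts by *coercing* the conflicting fixed
modification into the variable category, enumerating combinations of
variable modifications, pruning combinations that leave a coerced site
unmodified or put two modifications on one terminus, and finally reverting
coerced modifications back to fixed wherever no conflict remains.  Each
surviving combination is a :class:`ModSet`; per-set amino-acid mass
look-ups drive all downstream mass arithmetic.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from .constants import ELEMENT_MASSES, PHOSPHO_LOSS, RESIDUE_MASSES

POSITIONS = (
    "Anywhere",
    "Any N-term",
    "Any C-term",
    "Protein N-term",
    "Protein C-term",
)

N_TERM_POSITIONS = frozenset({"Any N-term", "Protein N-term"})
C_TERM_POSITIONS = frozenset({"Any C-term", "Protein C-term"})


class ModificationError(ValueError):
    """Raised for unknown symbols, bad grammar, or contradictory specs."""


_FORMULA_TOKEN = re.compile(r"(\d*[A-Z][a-z]*)(?:\((-?\d+)\))?")


def composition_mass(composition: str) -> float:
    """Monoisotopic mass (Da) of an elemental formula.

    The formula grammar follows Unimod composition strings: whitespace
    separated element tokens with optional integer counts in parentheses,
    e.g. ``"H(20) C(8) 13C(4) N 15N O(2)"``.  Counts may be negative
    (loss formulas such as ``"H(-3) N(-1)"``).
    """
    total = 0.0
    for token in composition.split():
        m = _FORMULA_TOKEN.fullmatch(token)
        if m is None:
            raise ModificationError(f"cannot parse composition token {token!r}")
        symbol, count = m.group(1), int(m.group(2) or 1)
        if symbol not in ELEMENT_MASSES:
            raise ModificationError(f"unknown element symbol {symbol!r}")
        total += count * ELEMENT_MASSES[symbol]
    return total


@dataclass(frozen=True)
class ModDefinition:
    """One registry entry: a modification at one site and position."""

    title: str
    site: str  # residue letter, or "N-term" / "C-term"
    position: str  # one of POSITIONS
    composition: str
    mono_mass: float
    neutral_losses: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.position not in POSITIONS:
            raise ModificationError(f"invalid position {self.position!r}")
        if abs(self.mono_mass - composition_mass(self.composition)) > 1e-4:
            raise ModificationError(
                f"{self.title}: mono_mass {self.mono_mass} does not match "
                f"composition {self.composition!r}"
            )

    @property
    def is_terminal(self) -> bool:
        return self.position != "Anywhere"

    @property
    def terminus(self) -> str | None:
        """'N-term' / 'C-term' for terminal entries, else None."""
        if self.position in N_TERM_POSITIONS:
            return "N-term"
        if self.position in C_TERM_POSITIONS:
            return "C-term"
        return None

    @property
    def conflict_key(self) -> str:
        """Key under which two modifications would collide chemically."""
        return self.terminus or self.site

    def label(self) -> str:
        if self.is_terminal and self.site in ("N-term", "C-term"):
            return f"{self.title} ({self.position.replace('Any ', '')})"
        if self.is_terminal:
            return f"{self.title} ({self.terminus} = {self.site})"
        return f"{self.title} ({self.site})"


def _mk(title, site, position, composition, nl=()) -> ModDefinition:
    return ModDefinition(
        title, site, position, composition, composition_mass(composition), nl
    )


def _default_entries() -> list[ModDefinition]:
    tmt10 = "H(20) C(8) 13C(4) N 15N O(2)"
    tmt0 = "H(20) C(12) N(2) O(2)"
    return [
        _mk("Carbamidomethyl", "C", "Anywhere", "H(3) C(2) N O"),
        _mk("Oxidation", "M", "Anywhere", "O"),
        _mk("Acetyl", "K", "Anywhere", "H(2) C(2) O"),
        _mk("Acetyl", "N-term", "Any N-term", "H(2) C(2) O"),
        _mk("Acetyl", "N-term", "Protein N-term", "H(2) C(2) O"),
        _mk("Deamidated", "N", "Anywhere", "H(-1) N(-1) O"),
        _mk("Deamidated", "Q", "Anywhere", "H(-1) N(-1) O"),
        _mk("Gln->pyro-Glu", "Q", "Any N-term", "H(-3) N(-1)"),
        _mk("TMT10plex", "K", "Anywhere", tmt10),
        _mk("TMT10plex", "N-term", "Any N-term", tmt10),
        _mk("TMT0", "K", "Anywhere", tmt0),
        _mk("TMT0", "N-term", "Any N-term", tmt0),
        _mk("Phospho", "S", "Anywhere", "H O(3) P", (PHOSPHO_LOSS,)),
        _mk("Phospho", "T", "Anywhere", "H O(3) P", (PHOSPHO_LOSS,)),
        _mk("Phospho", "Y", "Anywhere", "H O(3) P"),
        _mk("GG", "K", "Anywhere", "H(6) C(4) N(2) O(2)"),
        _mk("Carbamyl", "K", "Anywhere", "H C N O"),
        _mk("Carbamyl", "N-term", "Any N-term", "H C N O"),
        _mk("Label:13C(6)15N(2)", "K", "Anywhere", "C(-6) 13C(6) N(-2) 15N(2)"),
        _mk("Label:13C(6)15N(4)", "R", "Anywhere", "C(-6) 13C(6) N(-4) 15N(4)"),
    ]


class ModRegistry:
    """In-memory table of known modifications, extendable at run time."""

    def __init__(self, entries: list[ModDefinition] | None = None):
        self._entries: list[ModDefinition] = (
            list(entries) if entries is not None else _default_entries()
        )

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def add(
        self,
        title: str,
        site: str,
        position: str,
        composition: str,
        neutral_losses: tuple[float, ...] = (),
    ) -> ModDefinition:
        entry = _mk(title, site, position, composition, tuple(neutral_losses))
        self._entries.append(entry)
        return entry

    def add_composite(
        self, title: str, parts: list[ModDefinition], site: str, position: str
    ) -> ModDefinition:
        """Build an additive entry from several modifications of one site.

        Mirrors constructing a new registry entry for, e.g., a TMT label
        combined with pyro-glutamate formation at the peptide N-terminus.
        """
        composition = " ".join(p.composition for p in parts)
        losses = tuple(l for p in parts for l in p.neutral_losses)
        return self.add(title, site, position, composition, losses)

    def remove(self, title: str, site: str | None = None) -> int:
        before = len(self._entries)
        self._entries = [
            e
            for e in self._entries
            if not (e.title == title and (site is None or e.site == site))
        ]
        return before - len(self._entries)

    def find(
        self,
        title: str,
        site: str | None = None,
        position: str | None = None,
    ) -> list[ModDefinition]:
        return [
            e
            for e in self._entries
            if e.title == title
            and (site is None or e.site == site)
            and (position is None or e.position == position)
        ]

    # plain-text persistence -------------------------------------------------
    def to_table(self, path: str | Path) -> None:
        lines = ["title\tsite\tposition\tcomposition\tmono_mass\tneutral_losses"]
        for e in self._entries:
            nl = ",".join(f"{x:.6f}" for x in e.neutral_losses)
            lines.append(
                f"{e.title}\t{e.site}\t{e.position}\t{e.composition}"
                f"\t{e.mono_mass:.6f}\t{nl}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "ModRegistry":
        entries = []
        lines = Path(path).read_text().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            title, site, position, composition, _, nl = line.split("\t")
            losses = tuple(float(x) for x in nl.split(",") if x)
            entries.append(_mk(title, site, position, composition, losses))
        return cls(entries)


_SPEC = re.compile(r"^\s*(?P<title>.+?)\s*\(\s*(?P<where>[^)]+?)\s*\)\s*$")


def parse_mod_spec(text: str, registry: ModRegistry | None = None) -> ModDefinition:
    """Resolve a specification such as ``"Oxidation (M)"`` against the registry.

    Grammar: ``Title (site)``, ``Title (N-term)``, ``Title (Protein N-term)``
    or ``Title (N-term = Q)`` — the last form restricts an N-terminal
    modification to peptides starting with the given residue.
    """
    registry = registry if registry is not None else ModRegistry()
    m = _SPEC.match(text)
    if m is None:
        raise ModificationError(f"cannot parse modification spec {text!r}")
    title, where = m.group("title"), m.group("where")

    site: str | None
    position: str | None
    if "=" in where:
        left, right = (s.strip() for s in where.split("=", 1))
        if left not in ("N-term", "C-term") or len(right) != 1:
            raise ModificationError(f"bad terminal-site clause in {text!r}")
        site, position = right, f"Any {left}"
    elif where in ("N-term", "C-term"):
        site, position = where, f"Any {where}"
    elif where in ("Protein N-term", "Protein C-term"):
        site, position = where.split(" ", 1)[1], where
    elif len(where) == 1:
        site, position = where, "Anywhere"
    else:
        raise ModificationError(f"bad site/position clause in {text!r}")

    hits = registry.find(title, site=site, position=position)
    if not hits:
        raise ModificationError(
            f"no registry entry for title {title!r} at site {site!r}, "
            f"position {position!r}"
        )
    return hits[0]


@dataclass(frozen=True)
class ModSet:
    """One compiled combination of fixed and variable modifications.

    ``coerced`` lists modifications that were fixed in the user's
    specification but remain in the variable category within this set;
    ``required`` lists variable modifications that every site assignment
    must include (they displace a coerced fixed modification); and
    ``coverage_sites`` are sites/termini that must always end up modified.
    """

    fixed: tuple[ModDefinition, ...]
    variable: tuple[ModDefinition, ...]
    coerced: tuple[ModDefinition, ...] = ()
    required: tuple[ModDefinition, ...] = ()
    coverage_sites: tuple[str, ...] = ()
    set_index: int = 0

    def __post_init__(self) -> None:
        fixed_sites = {m.conflict_key for m in self.fixed}
        var_sites = {m.conflict_key for m in self.variable}
        # termini may legitimately carry a fixed mod while a residue-site
        # variable mod exists; the invariant is per conflict key
        clash = fixed_sites & var_sites
        if clash:
            raise ModificationError(
                f"site(s) {sorted(clash)} appear in both fixed and variable"
            )
        for fam, mods in (
            (N_TERM_POSITIONS, "N-term"),
            (C_TERM_POSITIONS, "C-term"),
        ):
            n = sum(1 for m in self.fixed + self.variable if m.position in fam)
            if n > 1:
                raise ModificationError(f"multiple {mods} modifications in one set")

    def signature(self) -> tuple:
        return (
            tuple(sorted((m.title, m.site, m.position) for m in self.fixed)),
            tuple(sorted((m.title, m.site, m.position) for m in self.variable)),
        )


def _conflicts_with_variable(f: ModDefinition, variable: list[ModDefinition]) -> bool:
    return any(f.conflict_key == v.conflict_key for v in variable)


def compile_mod_sets(
    fixed: list[ModDefinition], variable: list[ModDefinition]
) -> list[ModSet]:
    """Compile user fixed/variable modifications into minimal compatible sets.

    Rule chain:

    1. fixed modifications whose site (or terminus) also carries a variable
       modification are coerced to the variable category (``F_x``);
    2. all in/out combinations of the variable pool are enumerated
       (terminal options before Anywhere options, user order within each);
    3. combinations carrying two N-terminal (or two C-terminal)
       modifications are removed;
    4. combinations that leave a coerced site or terminus unmodified are
       removed — with several Anywhere coercions, every coerced site must
       be covered;
    5. within each surviving combination, a coerced modification reverts to
       fixed when no other modification competes for its site.
    """
    fixed = list(dict.fromkeys(fixed))
    variable = list(dict.fromkeys(variable))

    seen: dict[str, ModDefinition] = {}
    for f in fixed:
        if f.conflict_key in seen:
            raise ModificationError(
                f"two fixed modifications on site {f.conflict_key!r}: "
                f"{seen[f.conflict_key].title} and {f.title}"
            )
        seen[f.conflict_key] = f

    coerced = [f for f in fixed if _conflicts_with_variable(f, variable)]
    kept_fixed = [f for f in fixed if f not in coerced]

    # enumeration pool: coerced mods join the variable pool; terminal first
    pool = sorted(
        [(m, True) for m in coerced] + [(m, False) for m in variable],
        key=lambda t: 0 if t[0].is_terminal else 1,
    )
    coerced_keys = [m.conflict_key for m in coerced]

    sets: list[ModSet] = []
    signatures = set()
    for mask in itertools.product((True, False), repeat=len(pool)):
        combo = [pool[i] for i in range(len(pool)) if mask[i]]
        mods = [m for m, _ in combo]

        # rule 3: at most one modification per terminus
        if sum(1 for m in mods if m.position in N_TERM_POSITIONS) > 1:
            continue
        if sum(1 for m in mods if m.position in C_TERM_POSITIONS) > 1:
            continue

        # rule 4: every coerced site/terminus must be covered
        keys_in_combo = {m.conflict_key for m in mods}
        if any(k not in keys_in_combo for k in coerced_keys):
            continue

        # rule 5: revert coerced mods with no remaining competitor
        set_fixed = list(kept_fixed)
        set_variable: list[ModDefinition] = []
        still_coerced: list[ModDefinition] = []
        required: list[ModDefinition] = []
        for m, was_coerced in combo:
            competitors = [o for o, _ in combo if o is not m and o.conflict_key == m.conflict_key]
            if was_coerced and not competitors:
                set_fixed.append(m)
            else:
                set_variable.append(m)
                if was_coerced:
                    still_coerced.append(m)
                elif m.conflict_key in coerced_keys:
                    # this mod displaces a coerced fixed one: mandatory
                    required.append(m)

        modset = ModSet(
            fixed=tuple(set_fixed),
            variable=tuple(set_variable),
            coerced=tuple(still_coerced),
            required=tuple(required),
            coverage_sites=tuple(dict.fromkeys(coerced_keys)),
            set_index=len(sets),
        )
        if modset.signature() in signatures:
            continue
        signatures.add(modset.signature())
        sets.append(modset)
    return sets


@dataclass
class AminoAcidLookup:
    """Per-set mass look-up: (residue-or-terminus, modification title) -> Da.

    Unmodified residues use ``None`` as the modification key; fixed
    Anywhere modifications fold directly into the unmodified entry.
    Terminal keys hold mass *deltas* added to the peptide.  ``attrs``
    carries the positions, coercion flags and neutral-loss ("nl+") flags
    that downstream ion generation consults.
    """

    entries: dict[tuple[str, str | None], float] = field(default_factory=dict)
    attrs: dict[tuple[str, str | None], dict] = field(default_factory=dict)
    modset: ModSet | None = None

    def mass(self, site: str, title: str | None = None) -> float:
        return self.entries[(site, title)]

    def residue_titles(self, residue: str) -> list[str | None]:
        """Modification states available for a residue (None = unmodified)."""
        return [t for (s, t) in self.entries if s == residue]

    def has_neutral_loss(self, site: str, title: str | None) -> bool:
        return bool(self.attrs.get((site, title), {}).get("nl", ()))

    def neutral_losses(self, site: str, title: str | None) -> tuple[float, ...]:
        return self.attrs.get((site, title), {}).get("nl", ())


def build_aa_lookup(modset: ModSet) -> AminoAcidLookup:
    """Construct the amino-acid mass look-up for one modification set."""
    lk = AminoAcidLookup(modset=modset)

    for aa, m in RESIDUE_MASSES.items():
        lk.entries[(aa, None)] = m
        lk.attrs[(aa, None)] = {"position": "Anywhere", "variable": False,
                                "coerced": False, "nl": ()}
    for term in ("N-term", "C-term"):
        lk.entries[(term, None)] = 0.0
        lk.attrs[(term, None)] = {"position": None, "variable": False,
                                  "coerced": False, "nl": ()}

    for mod in modset.fixed:
        if mod.is_terminal:
            key = (mod.terminus, mod.title)
            lk.entries[key] = mod.mono_mass
            # a fixed terminal modification always applies: drop the bare entry
            del lk.entries[(mod.terminus, None)]
            del lk.attrs[(mod.terminus, None)]
        else:
            key = (mod.site, None)
            lk.entries[key] = RESIDUE_MASSES[mod.site] + mod.mono_mass
        lk.attrs[key] = {"position": mod.position, "variable": False,
                         "coerced": False, "nl": tuple(mod.neutral_losses),
                         "title": mod.title}

    for mod in modset.variable:
        if mod.is_terminal:
            key = (mod.terminus, mod.title)
            lk.entries[key] = mod.mono_mass
        else:
            key = (mod.site, mod.title)
            lk.entries[key] = RESIDUE_MASSES[mod.site] + mod.mono_mass
        lk.attrs[key] = {
            "position": mod.position,
            "variable": True,
            "coerced": mod in modset.coerced,
            "required": mod in modset.required,
            "nl": tuple(mod.neutral_losses),
            "title": mod.title,
            "site": mod.site,
        }
    return lk
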