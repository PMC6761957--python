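"""Character matrices and their recoding into presence/absence traits.

A morphological "characters × taxa" matrix scores each taxon for a set of
multistate categorical characters.  Recoding splits every character into one
column per state, so that each non-absence state becomes a *trait* — a node
of the trait network — supported by the set of taxa bearing that state.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

#: Canonical missing-data token used in :class:`CharacterMatrix` cells.
MISSING = "?"

__all__ = [
    "MISSING",
    "Character",
    "CharacterMatrix",
    "Trait",
    "TraitMatrix",
    "MatrixParseError",
    "default_absence_matcher",
    "parse_nexus",
    "parse_table",
    "recode",
    "write_trait_matrix",
    "read_trait_matrix",
]


class MatrixParseError(ValueError):
    """Raised when an input matrix document cannot be interpreted."""


@dataclass(frozen=True)
class Character:
    """One column of the input matrix: a homologous feature with discrete states.

    ``states`` maps each state symbol (e.g. ``"0"``) to a human-readable state
    label; unlabeled states carry their symbol as label.  Insertion order of
    ``states`` is the declared/observed symbol order and fixes trait ordering
    downstream.
    """

    character_id: int
    label: str
    states: dict[str, str]

    def __post_init__(self) -> None:
        if self.character_id < 1:
            raise ValueError("character_id is 1-based")
        if not self.states:
            raise ValueError(f"character {self.character_id} has no states")


@dataclass
class CharacterMatrix:
    """A taxa × characters matrix of state symbols (or :data:`MISSING`)."""

    taxa: tuple[str, ...]
    characters: tuple[Character, ...]
    #: object array of shape (n_taxa, n_characters) holding state symbols.
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.characters = tuple(self.characters)
        self.cells = np.asarray(self.cells, dtype=object)
        self.validate()

    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixParseError(f"duplicate taxon names: {dupes}")
        if not self.taxa:
            raise MatrixParseError("matrix has no taxa")
        if [c.character_id for c in self.characters] != list(
            range(1, len(self.characters) + 1)
        ):
            raise MatrixParseError("character ids must be contiguous from 1")
        if self.cells.shape != (len(self.taxa), len(self.characters)):
            raise MatrixParseError(
                f"cell block shape {self.cells.shape} does not match "
                f"{len(self.taxa)} taxa × {len(self.characters)} characters"
            )
        for j, ch in enumerate(self.characters):
            for i, taxon in enumerate(self.taxa):
                sym = self.cells[i, j]
                if sym != MISSING and sym not in ch.states:
                    raise MatrixParseError(
                        f"undeclared symbol {sym!r} for taxon {taxon!r}, "
                        f"character {ch.character_id}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def column(self, character_id: int) -> np.ndarray:
        return self.cells[:, character_id - 1]

    def encoded(self) -> np.ndarray:
        """Integer-coded cells: state index in declared order, −1 for missing."""
        out = np.empty(self.cells.shape, dtype=np.int64)
        for j, ch in enumerate(self.characters):
            index = {s: i for i, s in enumerate(ch.states)}
            index[MISSING] = -1
            out[:, j] = [index[s] for s in self.cells[:, j]]
        return out

    def with_cells(self, cells: np.ndarray) -> "CharacterMatrix":
        """Same taxa/characters with a replaced cell block (used by permutations)."""
        return CharacterMatrix(self.taxa, self.characters, cells)


@dataclass(frozen=True)
class Trait:
    """A single non-absence character state and the taxa that bear it."""

    node_id: int
    character_id: int
    state_symbol: str
    label: str
    support: frozenset[str]

    def __post_init__(self) -> None:
        if not self.support:
            raise ValueError(f"trait {self.node_id} has empty support")


@dataclass
class TraitMatrix:
    """Ordered trait list over a fixed taxon set; the trait-network node set."""

    taxa: tuple[str, ...]
    traits: tuple[Trait, ...]

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.traits = tuple(self.traits)
        taxset = set(self.taxa)
        seen: set[tuple[int, str]] = set()
        for i, tr in enumerate(self.traits, start=1):
            if tr.node_id != i:
                raise ValueError("node_ids must be 1..N in list order")
            key = (tr.character_id, tr.state_symbol)
            if key in seen:
                raise ValueError(f"duplicate trait for character/state {key}")
            seen.add(key)
            if not tr.support <= taxset:
                raise ValueError(
                    f"trait {tr.node_id} support contains unknown taxa "
                    f"{sorted(tr.support - taxset)}"
                )

    @property
    def N(self) -> int:
        """Number of traits (the symbol N of the density/triplet formulas)."""
        return len(self.traits)

    def incidence(self) -> np.ndarray:
        """Boolean (N × n_taxa) presence matrix, rows in node_id order."""
        tx_index = {t: i for i, t in enumerate(self.taxa)}
        out = np.zeros((self.N, len(self.taxa)), dtype=bool)
        for tr in self.traits:
            for t in tr.support:
                out[tr.node_id - 1, tx_index[t]] = True
        return out

    def trait_by_key(self, character_id: int, state_symbol: str) -> Trait:
        for tr in self.traits:
            if tr.character_id == character_id and tr.state_symbol == state_symbol:
                return tr
        raise KeyError((character_id, state_symbol))

    def character_of(self) -> np.ndarray:
        """character_id per node, aligned with node order (0-based array)."""
        return np.array([tr.character_id for tr in self.traits], dtype=np.int64)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_CHARSTATELABELS_RE = re.compile(
    r"CHARSTATELABELS\s+(.*?);", re.IGNORECASE | re.DOTALL
)


def _parse_charstatelabels(text: str) -> dict[int, tuple[str, list[str]]]:
    """Extract ``{char_number: (char_label, [state labels...])}`` from NEXUS text.

    dendropy reads the matrix itself but discards CHARSTATELABELS, so the
    labels are recovered here.  Entries look like
    ``1 skull_shape / flat round`` separated by commas.
    """
    m = _CHARSTATELABELS_RE.search(text)
    if not m:
        return {}
    out: dict[int, tuple[str, list[str]]] = {}
    for entry in m.group(1).split(","):
        entry = entry.strip()
        if not entry:
            continue
        if "/" in entry:
            head, _, tail = entry.partition("/")
            state_labels = [s.strip("'\" ") for s in tail.split()]
        else:
            head, state_labels = entry, []
        parts = head.split(None, 1)
        try:
            num = int(parts[0])
        except (ValueError, IndexError) as exc:
            raise MatrixParseError(
                f"malformed CHARSTATELABELS entry: {entry!r}"
            ) from exc
        label = parts[1].strip("'\" ").replace("_", " ") if len(parts) > 1 else str(num)
        out[num] = (label, [s.replace("_", " ") for s in state_labels])
    return out


def parse_nexus(text: str) -> CharacterMatrix:
    """Parse a NEXUS document with a DATA or CHARACTERS block.

    State symbols are preserved verbatim; cells equal to the document's
    MISSING symbol (or gaps) become :data:`MISSING`.  CHARSTATELABELS, when
    present, supply character and state labels; otherwise symbols stand in.
    """
    try:
        ds = dendropy.DataSet.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises several error classes
        raise MatrixParseError(f"NEXUS parse failed: {exc}") from exc
    if not ds.char_matrices:
        raise MatrixParseError("no CHARACTERS/DATA block found")
    dm = ds.char_matrices[0]
    taxa = tuple(t.label for t in dm.taxon_namespace)
    if not taxa:
        raise MatrixParseError("no taxa declared")
    ncols = max(len(dm[t]) for t in dm.taxon_namespace)
    cells = np.full((len(taxa), ncols), MISSING, dtype=object)
    for i, taxon in enumerate(dm.taxon_namespace):
        seq = dm[taxon]
        if len(seq) != ncols:
            raise MatrixParseError(
                f"taxon {taxon.label!r} has {len(seq)} cells, expected {ncols}"
            )
        for j, state in enumerate(seq):
            sym = str(state)
            cells[i, j] = MISSING if sym in ("?", "-") else sym

    labels = _parse_charstatelabels(text)
    characters = []
    for j in range(ncols):
        observed = [s for s in dict.fromkeys(sorted(set(cells[:, j]))) if s != MISSING]
        char_label, state_labels = labels.get(j + 1, (str(j + 1), []))
        states: dict[str, str] = {}
        for sym in observed:
            lab = sym
            # NEXUS state labels are positional over the symbol ordering 0,1,2…
            try:
                pos = int(sym)
                if 0 <= pos < len(state_labels):
                    lab = state_labels[pos]
            except ValueError:
                pass
            states[sym] = lab
        if not states:
            raise MatrixParseError(f"character {j + 1} has only missing data")
        characters.append(Character(j + 1, char_label, states))
    return CharacterMatrix(taxa, tuple(characters), cells)


def parse_table(
    text: str, *, delimiter: str = ",", missing_token: str = "?"
) -> CharacterMatrix:
    """Parse a delimited taxa × characters table (first column = taxon names)."""
    try:
        df = pd.read_csv(io.StringIO(text), sep=delimiter, header=None, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise MatrixParseError("empty table") from exc
    if df.empty or df.shape[1] < 2:
        raise MatrixParseError("empty or single-column table")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise MatrixParseError(f"ragged or incomplete row at index {bad}")
    taxa = tuple(df.iloc[:, 0].astype(str))
    cells = df.iloc[:, 1:].astype(str).to_numpy(dtype=object)
    cells[cells == missing_token] = MISSING
    characters = []
    for j in range(cells.shape[1]):
        observed = sorted(set(cells[:, j]) - {MISSING})
        if not observed:
            raise MatrixParseError(f"character {j + 1} has only missing data")
        characters.append(Character(j + 1, str(j + 1), {s: s for s in observed}))
    return CharacterMatrix(taxa, tuple(characters), cells)


# ---------------------------------------------------------------------------
# recoding
# ---------------------------------------------------------------------------

_ABSENT_RE = re.compile(r"absen", re.IGNORECASE)


def default_absence_matcher(symbol: str, label: str) -> bool:
    """Flag states whose *label* reads as an absence (e.g. "absent")."""
    return bool(_ABSENT_RE.search(label))


def recode(
    matrix: CharacterMatrix,
    absence_matcher=default_absence_matcher,
    *,
    min_taxa: int = 1,
) -> TraitMatrix:
    """Split each character into presence/absence traits, one per retained state.

    Every (character, state) pair whose state is not flagged by
    ``absence_matcher(symbol, label)`` and whose support — the taxa scored
    with that state — has at least ``min_taxa`` members becomes a trait.
    Missing cells contribute to no trait's support.  Traits are ordered by
    (character id, declared state order) and numbered 1..N.
    """
    if min_taxa < 1:
        raise ValueError("min_taxa must be ≥ 1")
    taxa = np.asarray(matrix.taxa, dtype=object)
    traits: list[Trait] = []
    n_missing = int(np.sum(matrix.cells == MISSING))
    if n_missing:
        warnings.warn(
            f"{n_missing} missing cell(s) treated as absence of all of that "
            "character's traits for the affected taxon"
        )
    for j, ch in enumerate(matrix.characters):
        col = matrix.cells[:, j]
        for sym, lab in ch.states.items():
            if absence_matcher is not None and absence_matcher(sym, lab):
                continue
            support = frozenset(taxa[col == sym])
            if len(support) < min_taxa:
                continue
            traits.append(
                Trait(
                    node_id=len(traits) + 1,
                    character_id=ch.character_id,
                    state_symbol=sym,
                    label=f"{ch.label}|'{lab}'",
                    support=support,
                )
            )
    if not traits:
        raise ValueError("empty trait set: all states filtered out")
    return TraitMatrix(matrix.taxa, tuple(traits))


# ---------------------------------------------------------------------------
# trait-table round trip
# ---------------------------------------------------------------------------


def write_trait_matrix(tm: TraitMatrix) -> str:
    """Serialize a TraitMatrix as headered TSV with one 0/1 column per taxon."""
    header = [
        "node_id",
        "character_id",
        "state_symbol",
        "label",
        "support_size",
        *tm.taxa,
    ]
    lines = ["\t".join(header)]
    for tr in tm.traits:
        row = [
            str(tr.node_id),
            str(tr.character_id),
            tr.state_symbol,
            tr.label,
            str(len(tr.support)),
            *("1" if t in tr.support else "0" for t in tm.taxa),
        ]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def read_trait_matrix(text: str) -> TraitMatrix:
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    fixed = ["node_id", "character_id", "state_symbol", "label", "support_size"]
    taxa = tuple(c for c in df.columns if c not in fixed)
    traits = []
    for _, row in df.iterrows():
        support = frozenset(t for t in taxa if row[t] == "1")
        traits.append(
            Trait(
                node_id=int(row["node_id"]),
                character_id=int(row["character_id"]),
                state_symbol=str(row["state_symbol"]),
                label=str(row["label"]),
                support=support,
            )
        )
    return TraitMatrix(taxa, tuple(traits))
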