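"""Specimen x character phenotype matrices.

Characters are binary, ordered multistate, or continuous morphometric.
Continuous measurements are gap-coded into ordered states before analysis;
missing cells ("?" or "-") carry a single missing flag — unknown and
inapplicable are not distinguished.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CodingError,
    DuplicateSpecimenError,
    StateOutOfRangeError,
    UnknownCharacterError,
)

MISSING_TOKENS = ("?", "-")

CHARACTER_KINDS = ("binary", "ordered_multistate", "continuous")


@dataclass(frozen=True)
class CharacterSpec:
    """Metadata for one phenotype character.

    Parameters
    ----------
    id:
        Short unique identifier (column header in matrix files).
    label:
        Free-text description.
    kind:
        ``binary``, ``ordered_multistate`` or ``continuous``.
    n_states:
        Number of coded states (>= 2). For continuous characters this is the
        number of ordered states produced by gap coding.
    category:
        Anatomical/ecological category, e.g. ``"thallus morphology"`` or
        ``"apothecia anatomy"``. Used for blockwise character subsets.
    coding_breaks:
        Strictly increasing thresholds for gap coding a continuous
        character; ``None`` requests automatic equal-width breaks.
    """

    id: str
    label: str = ""
    kind: str = "binary"
    n_states: int = 2
    category: str = ""
    coding_breaks: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.kind not in CHARACTER_KINDS:
            raise ValueError(f"unknown character kind {self.kind!r}")
        if self.n_states < 2:
            raise ValueError(f"character {self.id!r}: n_states must be >= 2")
        if self.kind == "binary" and self.n_states != 2:
            raise ValueError(f"binary character {self.id!r} must have n_states = 2")
        if self.coding_breaks is not None:
            br = tuple(float(b) for b in self.coding_breaks)
            if any(b2 <= b1 for b1, b2 in zip(br, br[1:])):
                raise ValueError(
                    f"character {self.id!r}: coding_breaks must be strictly increasing"
                )
            object.__setattr__(self, "coding_breaks", br)


def code_continuous(
    values: Sequence[float | None], spec: CharacterSpec
) -> list[int | None]:
    """Gap-code continuous measurements into ordered states.

    A value's state is the number of thresholds at or below it
    (right-half-open intervals: a value equal to a break belongs to the
    higher state). With automatic breaks, ``spec.n_states`` equal-width bins
    are laid over the observed non-missing range and the maximum falls in
    the top state. Missing values stay missing. The mapping is monotone
    non-decreasing in the measured value.
    """
    if spec.kind != "continuous":
        raise CodingError(f"character {spec.id!r} is not continuous")
    arr = np.array(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )
    finite = arr[~np.isnan(arr)]
    if np.any(np.isinf(arr)):
        raise CodingError(f"character {spec.id!r}: non-finite measurement")
    if spec.coding_breaks is not None:
        breaks = np.asarray(spec.coding_breaks, dtype=float)
    else:
        if finite.size == 0:
            raise CodingError(
                f"character {spec.id!r}: no observed values for automatic breaks"
            )
        lo, hi = finite.min(), finite.max()
        if hi == lo:  # degenerate range: everything is state 0
            return [None if np.isnan(v) else 0 for v in arr]
        breaks = lo + (hi - lo) / spec.n_states * np.arange(1, spec.n_states)
    states = np.searchsorted(breaks, arr, side="right")
    states = np.minimum(states, spec.n_states - 1)
    return [None if np.isnan(v) else int(s) for v, s in zip(arr, states)]


@dataclass
class CharacterMatrix:
    """Coded specimen x character matrix with missing-value mask.

    ``states`` holds non-negative integers; entries under ``missing_mask``
    are meaningless placeholders (0). ``is_reference`` marks specimens with
    sequence data (reference taxa); the rest are phenotype-only queries.
    """

    specimen_ids: list[str]
    taxon_labels: list[str]
    is_reference: np.ndarray  # bool, (n_specimens,)
    states: np.ndarray  # int, (n_specimens, n_characters)
    missing_mask: np.ndarray  # bool, same shape
    specs: list[CharacterSpec]
    is_type: np.ndarray | None = None  # optional type-material flags

    def __post_init__(self):
        self.is_reference = np.asarray(self.is_reference, dtype=bool)
        self.states = np.asarray(self.states, dtype=int)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.is_type is not None:
            self.is_type = np.asarray(self.is_type, dtype=bool)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    @property
    def n_characters(self) -> int:
        return len(self.specs)

    @property
    def character_ids(self) -> list[str]:
        return [s.id for s in self.specs]

    def validate(self) -> None:
        if len(set(self.specimen_ids)) != len(self.specimen_ids):
            dup = [s for s in set(self.specimen_ids) if self.specimen_ids.count(s) > 1]
            raise DuplicateSpecimenError(f"duplicate specimen ids: {sorted(dup)}")
        n, c = self.states.shape
        if n != len(self.specimen_ids) or c != len(self.specs):
            raise ValueError("states shape does not match ids/specs")
        if self.missing_mask.shape != self.states.shape:
            raise ValueError("missing_mask shape mismatch")
        for j, spec in enumerate(self.specs):
            col = self.states[:, j]
            obs = col[~self.missing_mask[:, j]]
            if obs.size and (obs.min() < 0 or obs.max() >= spec.n_states):
                bad = int(obs.max() if obs.max() >= spec.n_states else obs.min())
                raise StateOutOfRangeError(
                    f"character {spec.id!r}: state {bad} outside [0, {spec.n_states - 1}]"
                )

    def row(self, specimen_id: str) -> int:
        try:
            return self.specimen_ids.index(specimen_id)
        except ValueError:
            raise KeyError(f"unknown specimen id {specimen_id!r}") from None

    def char_index(self, char_id: str) -> int:
        for j, s in enumerate(self.specs):
            if s.id == char_id:
                return j
        raise UnknownCharacterError(f"unknown character id {char_id!r}")

    def subset_characters(self, char_ids: Iterable[str]) -> "CharacterMatrix":
        idx = [self.char_index(c) for c in char_ids]
        return CharacterMatrix(
            specimen_ids=list(self.specimen_ids),
            taxon_labels=list(self.taxon_labels),
            is_reference=self.is_reference.copy(),
            states=self.states[:, idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
            specs=[self.specs[j] for j in idx],
            is_type=None if self.is_type is None else self.is_type.copy(),
        )

    def subset_specimens(self, specimen_ids: Iterable[str]) -> "CharacterMatrix":
        idx = [self.row(s) for s in specimen_ids]
        return CharacterMatrix(
            specimen_ids=[self.specimen_ids[i] for i in idx],
            taxon_labels=[self.taxon_labels[i] for i in idx],
            is_reference=self.is_reference[idx],
            states=self.states[idx].copy(),
            missing_mask=self.missing_mask[idx].copy(),
            specs=list(self.specs),
            is_type=None if self.is_type is None else self.is_type[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        """States as a DataFrame with ``pd.NA`` in missing cells."""
        df = pd.DataFrame(
            self.states, index=self.specimen_ids, columns=self.character_ids
        ).astype("Int64")
        df = df.mask(pd.DataFrame(self.missing_mask, index=df.index, columns=df.columns))
        return df


# ---------------------------------------------------------------------------
# Character-spec sidecar CSV (id,label,kind,n_states,category[,coding_breaks])
# ---------------------------------------------------------------------------

def read_character_specs(path: str | Path) -> list[CharacterSpec]:
    df = pd.read_csv(path, dtype=str).fillna("")
    specs = []
    for _, r in df.iterrows():
        breaks = None
        if r.get("coding_breaks", ""):
            breaks = tuple(float(x) for x in str(r["coding_breaks"]).split(";"))
        specs.append(
            CharacterSpec(
                id=str(r["id"]),
                label=str(r.get("label", "")),
                kind=str(r.get("kind", "binary")) or "binary",
                n_states=int(r.get("n_states", 2) or 2),
                category=str(r.get("category", "")),
                coding_breaks=breaks,
            )
        )
    return specs


def write_character_specs(specs: Sequence[CharacterSpec], path: str | Path) -> None:
    rows = []
    for s in specs:
        rows.append(
            {
                "id": s.id,
                "label": s.label,
                "kind": s.kind,
                "n_states": s.n_states,
                "category": s.category,
                "coding_breaks": ";".join(str(b) for b in s.coding_breaks)
                if s.coding_breaks
                else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Matrix CSV: one header row of character ids; reserved leading columns
# specimen_id, taxon, is_reference[, is_type]; missing cells "?" or "-".
# ---------------------------------------------------------------------------

_RESERVED = ("specimen_id", "taxon", "is_reference", "is_type")


def read_character_matrix(
    path: str | Path,
    specs: Sequence[CharacterSpec] | None = None,
    format: str = "csv",
) -> CharacterMatrix:
    """Read a coded matrix from CSV or the NEXUS-style dialect.

    For CSV, character columns must match the provided ``specs`` ids (a
    sidecar ``<path>.specs.csv`` is read when ``specs`` is None). The
    NEXUS-style reader requires ``specs``.
    """
    if format == "nexus_like":
        if specs is None:
            raise UnknownCharacterError("NEXUS-style input requires character specs")
        return _read_nexus_like(path, list(specs))
    if format != "csv":
        raise ValueError(f"unknown matrix format {format!r}")
    path = Path(path)
    if specs is None:
        sidecar = path.with_suffix(path.suffix + ".specs.csv")
        if not sidecar.exists():
            sidecar = Path(str(path) + ".specs.csv")
        specs = read_character_specs(sidecar)
    specs = list(specs)
    df = pd.read_csv(path, dtype=str).fillna("?")
    by_id = {s.id: s for s in specs}
    char_cols = [c for c in df.columns if c not in _RESERVED]
    for c in char_cols:
        if c not in by_id:
            raise UnknownCharacterError(f"unknown character id {c!r} in {path}")
    ordered_specs = [by_id[c] for c in char_cols]
    n = len(df)
    states = np.zeros((n, len(char_cols)), dtype=int)
    missing = np.zeros_like(states, dtype=bool)
    for j, c in enumerate(char_cols):
        for i, raw in enumerate(df[c].astype(str).str.strip()):
            if raw in MISSING_TOKENS or raw == "":
                missing[i, j] = True
            else:
                states[i, j] = int(raw)
    ids = [str(x) for x in df["specimen_id"]]
    taxa = [str(x) for x in df["taxon"]] if "taxon" in df else list(ids)
    isref = (
        df["is_reference"].astype(str).str.strip().str.lower().isin(("1", "true", "yes")).to_numpy()
        if "is_reference" in df
        else np.ones(n, dtype=bool)
    )
    istype = (
        df["is_type"].astype(str).str.strip().str.lower().isin(("1", "true", "yes")).to_numpy()
        if "is_type" in df
        else None
    )
    return CharacterMatrix(ids, taxa, isref, states, missing, ordered_specs, istype)


def write_character_matrix(
    matrix: CharacterMatrix, path: str | Path, format: str = "csv",
    write_specs_sidecar: bool = True,
) -> None:
    if format == "nexus_like":
        Path(path).write_text(_to_nexus_like(matrix))
        return
    if format != "csv":
        raise ValueError(f"unknown matrix format {format!r}")
    path = Path(path)
    cells = matrix.states.astype(object)
    cells[matrix.missing_mask] = "?"
    df = pd.DataFrame(cells, columns=matrix.character_ids)
    df.insert(0, "specimen_id", matrix.specimen_ids)
    df.insert(1, "taxon", matrix.taxon_labels)
    df.insert(2, "is_reference", matrix.is_reference.astype(int))
    if matrix.is_type is not None:
        df.insert(3, "is_type", matrix.is_type.astype(int))
    df.to_csv(path, index=False)
    if write_specs_sidecar:
        write_character_specs(matrix.specs, Path(str(path) + ".specs.csv"))


# ---------------------------------------------------------------------------
# NEXUS-style CHARACTERS block dialect (SYMBOLS 0-9, MISSING ?)
# ---------------------------------------------------------------------------

def _to_nexus_like(matrix: CharacterMatrix) -> str:
    buf = _io.StringIO()
    buf.write("#NEXUS\nBEGIN CHARACTERS;\n")
    buf.write(
        f"  DIMENSIONS NTAX={matrix.n_specimens} NCHAR={matrix.n_characters};\n"
    )
    buf.write('  FORMAT SYMBOLS="0123456789" MISSING=?;\n  MATRIX\n')
    width = max(len(s) for s in matrix.specimen_ids) + 2
    for i, sid in enumerate(matrix.specimen_ids):
        row = "".join(
            "?" if matrix.missing_mask[i, j] else str(matrix.states[i, j])
            for j in range(matrix.n_characters)
        )
        buf.write(f"  {sid:<{width}}{row}\n")
    buf.write("  ;\nEND;\n")
    return buf.getvalue()


def _read_nexus_like(path: str | Path, specs: list[CharacterSpec]) -> CharacterMatrix:
    text = Path(path).read_text()
    m = re.search(r"MATRIX\s*(.*?);", text, re.S | re.I)
    if not m:
        raise UnknownCharacterError(f"no MATRIX block in {path}")
    ids, rows, masks = [], [], []
    for line in m.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        sid, seq = line.split(None, 1)
        seq = seq.replace(" ", "")
        if len(seq) != len(specs):
            raise StateOutOfRangeError(
                f"row {sid!r}: {len(seq)} cells for {len(specs)} characters"
            )
        ids.append(sid)
        rows.append([0 if ch in MISSING_TOKENS else int(ch) for ch in seq])
        masks.append([ch in MISSING_TOKENS for ch in seq])
    return CharacterMatrix(
        specimen_ids=ids,
        taxon_labels=list(ids),
        is_reference=np.ones(len(ids), dtype=bool),
        states=np.array(rows, dtype=int),
        missing_mask=np.array(masks, dtype=bool),
        specs=specs,
    )
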