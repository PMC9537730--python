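"""Reading, validating and indexing screening libraries and property tables.

A screening library is a fixed, ordered pool of candidate molecules. Each
molecule has a 0-based integer index (the canonical handle used everywhere
inside the package), an opaque string identifier used only at the I/O
boundary, and optionally a SMILES string. Numeric embeddings (pretrained
descriptors dumped as a matrix, or fingerprints computed here) bind to the
library by row order.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("moscreen")


class LibraryError(ValueError):
    """Raised for malformed library, embedding or property-table inputs."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule of the pool.

    ``smiles`` may be ``None`` in embedding-only mode (e.g. synthetic
    benchmarks), where nothing downstream needs chemistry.
    """

    index: int
    id: str
    smiles: str | None = None


@dataclass(frozen=True)
class ScreeningLibrary:
    """The fixed candidate pool: ordered records plus an optional embedding.

    Invariants: record indices are contiguous from 0, ids are unique, and the
    embedding matrix (when present) has exactly one finite row per record.
    """

    records: tuple[MoleculeRecord, ...]
    embeddings: np.ndarray | None = None
    embedding_name: str = ""

    def __post_init__(self) -> None:
        for pos, rec in enumerate(self.records):
            if rec.index != pos:
                raise LibraryError(
                    f"record at position {pos} carries index {rec.index}; "
                    "indices must be contiguous from 0"
                )
        ids = [rec.id for rec in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise LibraryError(f"duplicate molecule id {dup!r}")
        if self.embeddings is not None:
            emb = self.embeddings
            if emb.ndim != 2:
                raise LibraryError("embedding matrix must be 2-D")
            if emb.shape[0] != len(self.records):
                raise LibraryError(
                    f"row-count mismatch: {emb.shape[0]} embedding rows for "
                    f"{len(self.records)} records"
                )
            if emb.shape[1] < 1:
                raise LibraryError("embedding dimension must be >= 1")
            bad = ~np.isfinite(emb)
            if bad.any():
                row = int(np.nonzero(bad.any(axis=1))[0][0])
                raise LibraryError(f"non-finite embedding entry in row {row}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def d(self) -> int:
        if self.embeddings is None:
            raise LibraryError("library has no embeddings")
        return self.embeddings.shape[1]

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def index_of(self) -> dict[str, int]:
        return {rec.id: rec.index for rec in self.records}


@dataclass(frozen=True)
class PropertyTable:
    """One named raw property, keyed by molecule index.

    Covers either the whole library (precomputed mode) or exactly the
    evaluated subset (oracle mode).
    """

    property_name: str
    values: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for idx, val in self.values.items():
            if not np.isfinite(val):
                raise LibraryError(
                    f"non-finite value for index {idx} in property "
                    f"{self.property_name!r}"
                )

    def to_array(self, n: int) -> np.ndarray:
        """Dense vector over a full library; raises if coverage is partial."""
        out = np.full(n, np.nan)
        for idx, val in self.values.items():
            out[idx] = val
        if np.isnan(out).any():
            missing = int(np.nonzero(np.isnan(out))[0][0])
            raise LibraryError(
                f"property {self.property_name!r} does not cover index {missing}"
            )
        return out


def _validate_smiles(smiles: str) -> bool:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    return Chem.MolFromSmiles(smiles) is not None


def read_smiles_library(path: str | os.PathLike, strict: bool = True,
                        validate: bool = True) -> ScreeningLibrary:
    """Parse a ``.smi`` file: one molecule per line, ``SMILES [ID]``.

    Lines starting with ``#`` and blank lines are ignored. When the ID token
    is absent the (1-based) file line number is used. In strict mode a
    syntactically invalid SMILES or a duplicate ID raises; in lenient mode
    offending lines are skipped and counted in the log.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records: list[MoleculeRecord] = []
    seen_ids: set[str] = set()
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            smiles = tokens[0]
            mol_id = tokens[1] if len(tokens) > 1 else str(lineno)
            if validate and not _validate_smiles(smiles):
                if strict:
                    raise LibraryError(
                        f"invalid SMILES {smiles!r} at line {lineno}"
                    )
                skipped += 1
                continue
            if mol_id in seen_ids:
                if strict:
                    raise LibraryError(
                        f"duplicate id {mol_id!r} at line {lineno}"
                    )
                skipped += 1
                continue
            seen_ids.add(mol_id)
            records.append(MoleculeRecord(len(records), mol_id, smiles))
    if skipped:
        logger.info("read_smiles_library: skipped %d malformed/duplicate lines",
                    skipped)
    if not records:
        raise LibraryError("empty library")
    return ScreeningLibrary(tuple(records))


def library_from_arrays(ids: Sequence[str], embeddings: np.ndarray,
                        embedding_name: str = "synthetic") -> ScreeningLibrary:
    """Build an embedding-only library (no SMILES) from parallel arrays."""
    records = tuple(MoleculeRecord(i, str(mol_id)) for i, mol_id in enumerate(ids))
    return ScreeningLibrary(records, np.asarray(embeddings, dtype=float),
                            embedding_name)


def load_embeddings(library: ScreeningLibrary, path: str | os.PathLike,
                    embedding_name: str | None = None) -> ScreeningLibrary:
    """Bind a precomputed embedding matrix to ``library`` by row order.

    ``.npy`` loads as a binary array; anything else is parsed as delimited
    text (comma-delimited for ``.csv``, otherwise whitespace), no header.
    """
    path = os.fspath(path)
    if path.endswith(".npy"):
        matrix = np.load(path)
    elif path.endswith(".csv"):
        matrix = np.loadtxt(path, delimiter=",", ndmin=2)
    else:
        matrix = np.loadtxt(path, ndmin=2)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != len(library):
        raise LibraryError(
            f"row-count mismatch: matrix has {matrix.shape[0]} rows, "
            f"library has {len(library)} records"
        )
    name = embedding_name or os.path.splitext(os.path.basename(path))[0]
    return replace(library, embeddings=matrix, embedding_name=name)


def featurize_fingerprints(library: ScreeningLibrary, radius: int = 2,
                           n_bits: int = 2048) -> ScreeningLibrary:
    """Compute Morgan (ECFP-like) binary fingerprints as the embedding.

    Deterministic: identical SMILES always map to identical rows. A fallback
    when no pretrained continuous-descriptor matrix is available.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    rows = np.zeros((len(library), n_bits), dtype=float)
    for rec in library.records:
        if rec.smiles is None:
            raise LibraryError(f"record {rec.id!r} has no SMILES to featurize")
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise LibraryError(f"invalid SMILES {rec.smiles!r} for id {rec.id!r}")
        fp = gen.GetFingerprint(mol)
        rows[rec.index, list(fp.GetOnBits())] = 1.0
    return replace(library, embeddings=rows, embedding_name="fingerprint")


def read_property_table(path: str | os.PathLike, library: ScreeningLibrary,
                        column: str, id_column: str = "id",
                        require_full: bool = True) -> PropertyTable:
    """Read one property column from a CSV keyed by molecule identifier.

    CSV ids not present in the library are ignored (count logged). In
    full-coverage mode every library id must appear.
    """
    df = pd.read_csv(path)
    for col in (id_column, column):
        if col not in df.columns:
            raise LibraryError(f"column {col!r} missing from {path}")
    index_of = library.index_of()
    values: dict[int, float] = {}
    ignored = 0
    for row_no, (mol_id, raw) in enumerate(
            zip(df[id_column].astype(str), df[column]), start=2):
        idx = index_of.get(mol_id)
        if idx is None:
            ignored += 1
            continue
        try:
            val = float(raw)
        except (TypeError, ValueError):
            raise LibraryError(
                f"non-numeric value {raw!r} in column {column!r} at CSV row "
                f"{row_no}"
            ) from None
        if not np.isfinite(val):
            raise LibraryError(
                f"non-finite value in column {column!r} at CSV row {row_no}"
            )
        values[idx] = val
    if ignored:
        logger.info("read_property_table: ignored %d CSV ids not in library",
                    ignored)
    if require_full:
        missing = [rec.id for rec in library.records if rec.index not in values]
        if missing:
            shown = ", ".join(repr(m) for m in missing[:5])
            raise LibraryError(
                f"{len(missing)} library ids missing from {path}: {shown}"
                + ("..." if len(missing) > 5 else "")
            )
    return PropertyTable(column, values)


def write_property_table(path: str | os.PathLike, library: ScreeningLibrary,
                         tables: Sequence[PropertyTable],
                         id_column: str = "id") -> None:
    """Write property tables as CSV at full float precision (round-trips)."""
    indices = sorted(set().union(*(t.values.keys() for t in tables)))
    data: dict[str, list] = {id_column: [library.records[i].id for i in indices]}
    for table in tables:
        data[table.property_name] = [table.values[i] for i in indices]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
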