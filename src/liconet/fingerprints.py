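"""Compound parsing, circular (Morgan/ECFP) fingerprints and Dice similarity.

Compounds are hashed into fixed-length binary fingerprints encoding circular
atom environments (radius 2 by default).  Two bit lengths are used by the
pipeline: 2048 bits for the similarity matrix and 1024 bits for the 2-D
embedding, which consumes ``1 - Dice`` as its distance.  The Dice coefficient
between the on-bit sets *a* and *b* is ``2|a∩b| / (|a| + |b|)``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

# silence per-molecule RDKit parse chatter; failures are collected explicitly
RDLogger.DisableLog("rdApp.error")

SIMILARITY_NBITS = 2048
EMBEDDING_NBITS = 1024
DEFAULT_RADIUS = 2


@dataclass(frozen=True)
class Compound:
    """A named molecule identified by its SMILES string."""

    id: str
    name: str
    smiles: str


@dataclass(frozen=True)
class Fingerprint:
    """Hashed circular fingerprint as a set of on-bit indices."""

    on_bits: frozenset[int]
    nbits: int
    radius: int = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if self.on_bits and (min(self.on_bits) < 0 or max(self.on_bits) >= self.nbits):
            raise ValueError("bit index outside [0, nbits)")

    def __len__(self) -> int:
        return len(self.on_bits)

    def to_hex(self) -> str:
        """Serialize to a hex string (MSB-first within each byte)."""
        if self.nbits % 8:
            raise ValueError("hex serialization requires nbits divisible by 8")
        buf = bytearray(self.nbits // 8)
        for b in self.on_bits:
            buf[b // 8] |= 0x80 >> (b % 8)
        return buf.hex()

    @classmethod
    def from_hex(cls, hexstring: str, nbits: int, radius: int = DEFAULT_RADIUS) -> "Fingerprint":
        buf = bytes.fromhex(hexstring)
        if len(buf) * 8 != nbits:
            raise ValueError(f"hex string encodes {len(buf) * 8} bits, expected {nbits}")
        on = frozenset(
            i * 8 + j for i, byte in enumerate(buf) if byte for j in range(8) if byte & (0x80 >> j)
        )
        return cls(on_bits=on, nbits=nbits, radius=radius)


@dataclass
class ParseResult:
    """Compounds parsed from a table plus per-row errors for skipped rows."""

    compounds: list[Compound]
    errors: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self.compounds)

    def __len__(self) -> int:
        return len(self.compounds)

    def __getitem__(self, i):
        return self.compounds[i]


@dataclass
class SimilarityMatrix:
    """Symmetric Dice-similarity matrix over an ordered compound id list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match id count")

    def loc(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def parse_smiles_table(source: str | Path | io.TextIOBase) -> ParseResult:
    """Parse a delimited compound table into :class:`Compound` records.

    The table needs a SMILES column and a name column; a header row is
    detected from the column labels (``name``/``smiles``, case-insensitive),
    otherwise the first two columns are taken positionally as name, SMILES.
    Rows with unparseable SMILES are skipped and reported in ``errors``;
    duplicate structures (same canonical SMILES) keep the first occurrence.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return ParseResult(compounds=[])

    sep = "\t" if "\t" in lines[0] else ","
    header = [c.strip().lower() for c in lines[0].split(sep)]
    name_col, smiles_col, id_col = 0, 1, None
    data_lines = lines
    if "smiles" in header:
        smiles_col = header.index("smiles")
        for cand in ("name", "molecule name", "compound"):
            if cand in header:
                name_col = header.index(cand)
                break
        if "id" in header:
            id_col = header.index("id")
        data_lines = lines[1:]

    compounds: list[Compound] = []
    errors: list[str] = []
    seen: dict[str, str] = {}
    for rowno, line in enumerate(data_lines, start=1):
        fields = [c.strip() for c in line.split(sep)]
        if len(fields) <= max(name_col, smiles_col):
            errors.append(f"row {rowno}: expected at least {max(name_col, smiles_col) + 1} columns")
            continue
        name, smiles = fields[name_col], fields[smiles_col]
        canon = _canonical(smiles)
        if canon is None:
            errors.append(f"row {rowno}: unparseable SMILES {smiles!r}")
            continue
        if canon in seen:
            logger.warning("duplicate structure %r (same as %r); keeping first", name, seen[canon])
            continue
        seen[canon] = name
        cid = fields[id_col] if id_col is not None else name
        compounds.append(Compound(id=cid, name=name, smiles=smiles))

    ids = [c.id for c in compounds]
    if len(set(ids)) != len(ids):
        raise ValueError("compound ids are not unique after parsing")
    return ParseResult(compounds=compounds, errors=errors)


def morgan_fingerprint(
    compound: Compound | str,
    radius: int = DEFAULT_RADIUS,
    nbits: int = SIMILARITY_NBITS,
    *,
    use_chirality: bool = False,
) -> Fingerprint:
    """Hashed circular fingerprint of a compound (or bare SMILES string).

    Chirality is ignored by default; pass ``use_chirality=True`` to fold
    stereo flags into the environment hashes.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if nbits < 64:
        raise ValueError("nbits must be >= 64")
    smiles = compound.smiles if isinstance(compound, Compound) else compound
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid molecule: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=nbits, includeChirality=use_chirality
    )
    bv = gen.GetFingerprint(mol)
    return Fingerprint(on_bits=frozenset(bv.GetOnBits()), nbits=nbits, radius=radius)


def dice_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Dice coefficient ``2|a∩b| / (|a| + |b|)`` between two fingerprints."""
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint lengths differ: {a.nbits} vs {b.nbits}")
    denom = len(a.on_bits) + len(b.on_bits)
    if denom == 0:
        raise ValueError("Dice similarity undefined for two empty fingerprints")
    return 2.0 * len(a.on_bits & b.on_bits) / denom


def similarity_matrix(
    fps: Sequence[Fingerprint] | Mapping[str, Fingerprint],
    ids: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """All-pairs Dice similarity with unit diagonal."""
    if isinstance(fps, Mapping):
        ids = list(fps.keys())
        fp_list = [fps[i] for i in ids]
    else:
        fp_list = list(fps)
        if ids is None:
            ids = [str(i) for i in range(len(fp_list))]
    n = len(fp_list)
    if n < 1:
        raise ValueError("similarity matrix requires at least one fingerprint")
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dice_similarity(fp_list[i], fp_list[j])
    return SimilarityMatrix(ids=list(ids), values=values)


# ---------------------------------------------------------------------------
# file I/O


def write_fingerprints(
    fps: Mapping[str, Fingerprint], path: str | Path
) -> None:
    """Write a fingerprint table (``id``, ``nbits``, ``radius``, ``hex``)."""
    rows = [
        {"id": cid, "nbits": fp.nbits, "radius": fp.radius, "hex": fp.to_hex()}
        for cid, fp in fps.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fingerprints(path: str | Path) -> dict[str, Fingerprint]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "hex": str})
    radius = df["radius"] if "radius" in df.columns else [DEFAULT_RADIUS] * len(df)
    return {
        str(row.id): Fingerprint.from_hex(row.hex, int(row.nbits), int(r))
        for (_, row), r in zip(df.iterrows(), radius)
    }


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    sim.to_frame().to_csv(path, sep="\t", index_label="id")


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    df.index = df.index.astype(str)
    return SimilarityMatrix(ids=[str(c) for c in df.columns], values=df.to_numpy())


def packaged_compound_table() -> Path:
    """Path of the packaged licorice-flavonoid compound table."""
    return Path(__file__).parent / "data" / "licorice_flavonoids.tsv"
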