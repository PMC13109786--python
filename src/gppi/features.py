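"""Residue-level physicochemical features.

Each of the 20 standard amino acids is described by five properties —
hydrophobicity, van der Waals volume, polarizability, isoelectric point (pI)
and dissociation constant (pKa) — min-max normalized to [0, 1] over the 20
residues, so 1.0 always means "the residue with the strongest expression of
this property".

The shipped default table combines published scales (Kyte–Doolittle
hydropathy, Darby/Creighton van der Waals volumes, Charton–Charton
polarizability, standard free-amino-acid pKa values). pI is derived as the
mean of the two pKa values flanking the neutral species:
``pI = (pKa1 + pKa2) / 2`` using the side-chain pKa in place of the backbone
value for residues with an ionizable side chain. The pKa feature uses the
side-chain pKa where one exists and the alpha-carboxyl pKa otherwise, as a
proxy for protonation behaviour near physiological pH.

The raw scale values are a configurable input (``load_raw_properties`` /
``build_property_table``); the default lives in ``data/aa_properties.tsv``
so results are reproducible against a versioned file.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateScaleError, EncodingError

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
PROPERTY_NAMES = ("hydrophobicity", "volume", "polarizability", "pI", "pKa")

#: residues whose side chain carries a titratable group that flanks the
#: neutral species on the acidic side (pKa_side < pKa_amino)
_ACIDIC_SIDE = frozenset("DEC")
#: residues whose titratable side chain flanks on the basic side
_BASIC_SIDE = frozenset("HKR")


@dataclass(frozen=True)
class PropertyTable:
    """20 x 5 matrix of normalized residue properties.

    Rows are ordered as :data:`AMINO_ACIDS`; every value lies in [0, 1] and
    each column attains 0 and 1 exactly once (min-max normalization).
    """

    values: np.ndarray  # (20, 5) float64
    codes: str = AMINO_ACIDS
    columns: tuple = PROPERTY_NAMES

    def __post_init__(self):
        if self.values.shape != (20, 5):
            raise ValueError(f"expected a 20x5 table, got {self.values.shape}")

    def row(self, code: str) -> np.ndarray:
        idx = self.codes.find(code)
        if idx < 0:
            raise EncodingError(f"residue code {code!r} not in property table")
        return self.values[idx]

    def version_hash(self) -> str:
        """Stable content hash, stored in model checkpoints."""
        return hashlib.sha256(
            np.ascontiguousarray(self.values, dtype=np.float64).tobytes()
        ).hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.codes), columns=self.columns)

    def save(self, path) -> None:
        """Serialize as a 21-line delimited file (header + 20 rows)."""
        df = self.to_frame()
        df.index.name = "code"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def load(cls, path) -> "PropertyTable":
        df = pd.read_csv(path, sep="\t", index_col="code")
        df = df.loc[list(AMINO_ACIDS), list(PROPERTY_NAMES)]
        return cls(values=df.to_numpy(dtype=np.float64))


def load_raw_properties(path=None) -> pd.DataFrame:
    """Read a raw (un-normalized) property file.

    Columns: hydropathy, vdw_volume, polarizability, pka_carboxyl,
    pka_amino, pka_side (NA where the side chain is not ionizable).
    """
    if path is None:
        with resources.as_file(
            resources.files("gppi.data").joinpath("aa_properties.tsv")
        ) as p:
            return load_raw_properties(p)
    df = pd.read_csv(Path(path), sep="\t", comment="#", index_col="code")
    missing = set(AMINO_ACIDS) - set(df.index)
    if missing:
        raise ValueError(f"raw property table missing residues: {sorted(missing)}")
    return df.loc[list(AMINO_ACIDS)]


def isoelectric_point(code: str, pka_carboxyl: float, pka_amino: float,
                      pka_side: float) -> float:
    """pI as the mean of the two pKa values flanking the neutral form."""
    if code in _ACIDIC_SIDE:
        return (pka_carboxyl + pka_side) / 2.0
    if code in _BASIC_SIDE:
        return (pka_amino + pka_side) / 2.0
    return (pka_carboxyl + pka_amino) / 2.0


def _minmax(col: np.ndarray, name: str) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi == lo:
        raise DegenerateScaleError(f"property column {name!r} is constant")
    return (col - lo) / (hi - lo)


def build_property_table(raw: pd.DataFrame | None = None) -> PropertyTable:
    """Assemble the normalized 20x5 table from raw scale values.

    Parameters
    ----------
    raw:
        Frame indexed by one-letter code with the columns produced by
        :func:`load_raw_properties`. Defaults to the shipped table.
    """
    if raw is None:
        raw = load_raw_properties()
    raw = raw.loc[list(AMINO_ACIDS)]
    pka_side = raw["pka_side"].to_numpy(dtype=float)  # NaN where absent
    pka1 = raw["pka_carboxyl"].to_numpy(dtype=float)
    pka2 = raw["pka_amino"].to_numpy(dtype=float)
    pi = np.array([
        isoelectric_point(code, pka1[i], pka2[i], pka_side[i])
        for i, code in enumerate(AMINO_ACIDS)
    ])
    # pKa feature: side-chain value where ionizable, alpha-carboxyl otherwise
    pka_feat = np.where(np.isnan(pka_side), pka1, pka_side)
    cols = {
        "hydrophobicity": raw["hydropathy"].to_numpy(dtype=float),
        "volume": raw["vdw_volume"].to_numpy(dtype=float),
        "polarizability": raw["polarizability"].to_numpy(dtype=float),
        "pI": pi,
        "pKa": pka_feat,
    }
    values = np.column_stack([
        _minmax(cols[name], name) for name in PROPERTY_NAMES
    ])
    return PropertyTable(values=values)


_DEFAULT_TABLE: PropertyTable | None = None


def default_property_table() -> PropertyTable:
    """The shipped default table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = build_property_table()
    return _DEFAULT_TABLE


def encode_residues(structure, table: PropertyTable | None = None) -> np.ndarray:
    """Node feature matrix (n x 5) for a structure: row i = table row of
    residue i's one-letter code."""
    if table is None:
        table = default_property_table()
    idx = []
    for res in structure.residues:
        j = table.codes.find(res.code)
        if j < 0:
            raise EncodingError(
                f"residue {res.code}{res.seq_index} of {structure.protein_id} "
                "is not in the property table"
            )
        idx.append(j)
    return table.values[np.array(idx, dtype=int)]
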