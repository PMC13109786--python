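"""Reading protein structures into standardized residue records.

A structure is reduced to its Calpha trace: one record per residue with a
one-letter code, chain id, author residue number and the Calpha coordinates
in Angstrom. That is all the contact-graph construction needs. PDB and mmCIF
documents are parsed with gemmi; only the first model is used, alternate
locations are resolved to the highest-occupancy conformer (ties by altloc
identifier), residues without a Calpha are dropped, and non-standard residues
are mapped to their canonical parent (selenomethionine -> M, ...) where a
mapping exists.

Predicted models can be fetched by UniProt accession from a configurable
remote repository (default: the AlphaFold database), with a mandatory local
cache and offline mode: nothing is ever downloaded unless explicitly allowed.
"""

from __future__ import annotations

import logging
import re
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import gemmi
import numpy as np

from .errors import (
    AccessionError,
    EmptyStructureError,
    NotFoundError,
    OfflineError,
    StructureFormatError,
)

log = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: canonical-parent mapping for common non-standard residues
NONSTANDARD_PARENT = {
    "MSE": "M",  # selenomethionine
    "SEC": "C",  # selenocysteine -> cysteine parent
    "PYL": "K",  # pyrrolysine -> lysine parent
    "HYP": "P",  # hydroxyproline
    "MLY": "K", "M3L": "K", "KCX": "K",
    "CSO": "C", "CSD": "C", "CME": "C", "OCS": "C",
    "PTR": "Y", "SEP": "S", "TPO": "T",
    "FME": "M", "MLE": "L", "AIB": "A", "DAL": "A",
}

UNIPROT_ACCESSION_RE = re.compile(
    r"^[OPQ][0-9][A-Z0-9]{3}[0-9]$|^[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2}$"
)

#: AlphaFold database URL template; ``{accession}`` is substituted
DEFAULT_FETCH_URL = "https://alphafold.ebi.ac.uk/files/AF-{accession}-F1-model_v4.pdb"


@dataclass(frozen=True)
class ResidueRecord:
    """One residue of a Calpha trace."""

    code: str           # one-letter code, one of the 20 standard residues
    chain_id: str
    seq_index: int      # author residue number from the file
    ca_coord: np.ndarray  # (3,) float64, Angstrom

    def __post_init__(self):
        if self.code not in THREE_TO_ONE.values():
            raise ValueError(f"non-standard one-letter code {self.code!r}")
        coord = np.asarray(self.ca_coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError("ca_coord must be a finite 3-vector")
        object.__setattr__(self, "ca_coord", coord)

    @property
    def label(self) -> str:
        """Token like ``K45`` used in reports and saliency maps."""
        return f"{self.code}{self.seq_index}"


@dataclass
class ProteinStructure:
    """Ordered Calpha trace of one protein (possibly multi-chain)."""

    protein_id: str
    residues: list[ResidueRecord]
    source: Literal["experimental", "predicted", "synthetic"] = "experimental"

    def __post_init__(self):
        if len(self.residues) < 2:
            raise EmptyStructureError(
                f"{self.protein_id}: a structure needs at least 2 residues "
                f"with a Calpha (got {len(self.residues)})"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.stack([r.ca_coord for r in self.residues])

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.residues]


def extract_sequence(structure: ProteinStructure) -> str:
    """Concatenated one-letter codes in residue order."""
    return "".join(r.code for r in structure.residues)


def _pick_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy Calpha; occupancy ties broken by altloc order."""
    cas = [a for a in residue if a.name == "CA" and a.element.name != "Ca"]
    if not cas:
        return None
    return min(cas, key=lambda a: (-a.occ, a.altloc))


def parse_structure(file_text: str, format: str = "pdb",
                    protein_id: str = "protein",
                    source: str = "experimental") -> ProteinStructure:
    """Parse PDB or mmCIF text into a :class:`ProteinStructure`.

    Residues without a Calpha atom are dropped; non-standard residues are
    mapped to a canonical parent where known and dropped (with a warning)
    otherwise. Only the first model is read.
    """
    try:
        if format == "pdb":
            st = gemmi.read_pdb_string(file_text)
        elif format == "mmcif":
            doc = gemmi.cif.read_string(file_text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown structure format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{protein_id}: cannot parse {format} "
                                   f"document: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{protein_id}: document contains no model")
    st.setup_entities()
    model = st[0]
    residues: list[ResidueRecord] = []
    for chain in model:
        # keep file order; ties from insertion codes preserve document order
        for res in chain:
            name = res.name.upper()
            code = THREE_TO_ONE.get(name) or NONSTANDARD_PARENT.get(name)
            if code is None:
                info = gemmi.find_tabulated_residue(name)
                if info is not None and info.is_amino_acid():
                    # non-standard amino acid without a canonical parent
                    log.warning("%s: dropping unmapped residue %s %s%s",
                                protein_id, name, chain.name, res.seqid.num)
                continue  # water / ligand / nucleic acid: ignored silently
            ca = _pick_ca(res)
            if ca is None:
                continue
            residues.append(ResidueRecord(
                code=code,
                chain_id=chain.name,
                seq_index=res.seqid.num,
                ca_coord=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
            ))
    if not residues:
        raise EmptyStructureError(
            f"{protein_id}: no residues with a Calpha atom after filtering")
    return ProteinStructure(protein_id=protein_id, residues=residues,
                            source=source)


def parse_structure_file(path, protein_id: str | None = None,
                         source: str = "experimental") -> ProteinStructure:
    """Parse a structure file, inferring the format from its suffix."""
    path = Path(path)
    fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    pid = protein_id or path.stem
    return parse_structure(path.read_text(), format=fmt, protein_id=pid,
                           source=source)


def write_pdb(structure: ProteinStructure) -> str:
    """Minimal Calpha-only PDB text (3-decimal coordinates).

    Used for fixtures and for exporting synthetic worlds; round-trips
    through :func:`parse_structure` up to coordinate precision.
    """
    one_to_three = {v: k for k, v in THREE_TO_ONE.items()}
    lines = []
    for i, res in enumerate(structure.residues, start=1):
        x, y, z = res.ca_coord
        lines.append(
            f"ATOM  {i:5d}  CA  {one_to_three[res.code]} "
            f"{res.chain_id:>1}{res.seq_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@dataclass
class FetchConfig:
    """Where and how predicted models are fetched."""

    url_template: str = DEFAULT_FETCH_URL
    file_ext: str = "pdb"
    timeout: float = 30.0
    allow_network: bool = False


def fetch_structure(accession: str, cache_dir,
                    config: FetchConfig = FetchConfig()) -> str:
    """Return structure-file text for a UniProt accession.

    A cached copy in ``cache_dir`` is always preferred; the remote
    repository is contacted only when ``config.allow_network`` is set.
    """
    if not UNIPROT_ACCESSION_RE.match(accession):
        raise AccessionError(f"{accession!r} is not a UniProt accession")
    cache_dir = Path(cache_dir)
    cache_file = cache_dir / f"{accession}.{config.file_ext}"
    if cache_file.exists():
        return cache_file.read_text()
    if not config.allow_network:
        raise OfflineError(
            f"{accession}: not cached in {cache_dir} and network access is "
            "disabled (pass allow_network=True / --fetch to enable)")
    url = config.url_template.format(accession=accession)
    try:
        with urllib.request.urlopen(url, timeout=config.timeout) as resp:
            text = resp.read().decode()
    except urllib.error.HTTPError as exc:
        if exc.code == 404:
            raise NotFoundError(
                f"no predicted model found for accession {accession}") from exc
        raise
    cache_dir.mkdir(parents=True, exist_ok=True)
    cache_file.write_text(text)
    return text
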