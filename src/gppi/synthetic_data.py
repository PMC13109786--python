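"""Fully synthetic proteins and interaction labels with planted ground truth.

The generator emulates just enough of a structural PPI dataset to exercise
every stage of the pipeline offline:

* **Backbones** are random persistent self-avoiding walks with exact 3.8 A
  consecutive Calpha spacing and a 4.0 A minimum clearance between
  non-consecutive residues — geometrically plausible Calpha traces, not
  folded proteins.
* **Sticky patches**: a configurable fraction of proteins carries a planted
  contiguous run of ``patch_size`` residues rewritten to the
  maximum-hydrophobicity residue (isoleucine under the default table), while
  the background sequence is drawn only from residues whose normalized
  hydrophobicity stays below 0.9. A pair interacts (label 1) iff BOTH
  proteins carry a patch, so the rule is exactly separable from the node
  features alone, and the patch residues are the ground-truth hotspots.
* **Pairs** are sampled to an exact 50/50 label balance, mirroring the
  near-balanced design of curated interaction datasets.

Because the patch is contiguous in sequence (hence spatially localized on
the walk), recovering it by saliency is a meaningful test of the
explanation machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, GppiError
from .features import AMINO_ACIDS, default_property_table
from .structure_io import ProteinStructure, ResidueRecord, write_pdb
from .training import LabeledPair, write_pairs

#: residue used for planted patches: the hydrophobicity-scale maximum
STICKY_CODE = "I"


def _background_alphabet(hydrophobicity_max: float = 0.9) -> str:
    """Residues whose normalized hydrophobicity is below the oracle cutoff."""
    table = default_property_table()
    col = table.values[:, table.columns.index("hydrophobicity")]
    return "".join(c for c, v in zip(AMINO_ACIDS, col) if v <= hydrophobicity_max)


@dataclass(frozen=True)
class SyntheticConfig:
    n_proteins: int = 200
    length_range: tuple = (30, 60)   # residues, inclusive bounds
    ca_spacing: float = 3.8          # A between consecutive Calphas
    min_clearance: float = 4.0       # A between non-consecutive Calphas
    patch_size: int = 8
    patch_fraction: float = 0.5
    n_pairs: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.length_range[0] < self.patch_size:
            raise ConfigError("minimum length must be >= patch_size")
        if self.ca_spacing <= 0:
            raise ConfigError("ca_spacing must be positive")
        if not (0.0 <= self.patch_fraction <= 1.0):
            raise ConfigError("patch_fraction must be in [0, 1]")


def _walk(length: int, rng: np.random.Generator, spacing: float,
          clearance: float, max_restarts: int = 20) -> np.ndarray:
    """Persistent random walk with exact step length and clash avoidance."""
    clearance2 = clearance * clearance
    for _ in range(max_restarts):
        coords = np.zeros((length, 3))
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        ok = True
        for i in range(1, length):
            placed = False
            for _attempt in range(60):
                # persistence keeps the chain locally straight, which makes
                # clash-free placement easy at 3.8 A steps
                proposal = direction + 0.8 * rng.standard_normal(3)
                proposal /= np.linalg.norm(proposal)
                pos = coords[i - 1] + spacing * proposal
                if i >= 2:
                    d2 = ((coords[: i - 1] - pos) ** 2).sum(axis=1)
                    if d2.min() < clearance2:
                        continue
                coords[i] = pos
                direction = proposal
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return coords
    raise GppiError(f"failed to place a clash-free {length}-residue chain; "
                    "re-seed the generator")


def generate_chain(length: int, seed: int, ca_spacing: float = 3.8,
                   min_clearance: float = 4.0, protein_id: str = "SYN",
                   codes: str | None = None,
                   rng: np.random.Generator | None = None) -> ProteinStructure:
    """One synthetic Calpha trace with random residue codes."""
    if length < 2:
        raise ConfigError("chain length must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    alphabet = codes if codes is not None else AMINO_ACIDS
    coords = _walk(length, rng, ca_spacing, min_clearance)
    seq = rng.choice(list(alphabet), size=length)
    residues = [
        ResidueRecord(code=str(seq[i]), chain_id="A", seq_index=i + 1,
                      ca_coord=coords[i])
        for i in range(length)
    ]
    return ProteinStructure(protein_id=protein_id, residues=residues,
                            source="synthetic")


@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    structures: dict[str, ProteinStructure]
    pairs: list[LabeledPair]
    hotspot_truth: dict[str, list[str]]  # patch residue labels; [] if no patch

    @property
    def patched_ids(self) -> list[str]:
        return sorted(pid for pid, h in self.hotspot_truth.items() if h)


def generate_world(config: SyntheticConfig = SyntheticConfig()) -> SyntheticWorld:
    """Structures, balanced labeled pairs and ground-truth hotspots."""
    rng = np.random.default_rng(config.seed)
    background = _background_alphabet()
    n = config.n_proteins
    lo, hi = config.length_range
    n_patched = int(round(config.patch_fraction * n))
    patched = np.zeros(n, dtype=bool)
    patched[rng.permutation(n)[:n_patched]] = True

    structures: dict[str, ProteinStructure] = {}
    hotspot_truth: dict[str, list[str]] = {}
    ids = [f"SYN{i:04d}" for i in range(n)]
    for i, pid in enumerate(ids):
        length = int(rng.integers(lo, hi + 1))
        st = generate_chain(length, seed=0, ca_spacing=config.ca_spacing,
                            min_clearance=config.min_clearance,
                            protein_id=pid, codes=background, rng=rng)
        if patched[i]:
            start = int(rng.integers(0, length - config.patch_size + 1))
            for j in range(start, start + config.patch_size):
                r = st.residues[j]
                st.residues[j] = ResidueRecord(
                    code=STICKY_CODE, chain_id=r.chain_id,
                    seq_index=r.seq_index, ca_coord=r.ca_coord)
            hotspot_truth[pid] = [st.residues[j].label
                                  for j in range(start, start + config.patch_size)]
        else:
            hotspot_truth[pid] = []
        structures[pid] = st

    # balanced pair sampling: positives need two patched proteins
    n_pos = config.n_pairs // 2
    n_neg = config.n_pairs - n_pos
    patched_ids = [ids[i] for i in range(n) if patched[i]]
    plain_ids = [ids[i] for i in range(n) if not patched[i]]
    max_pos = len(patched_ids) * (len(patched_ids) - 1) // 2
    if n_pos > max_pos:
        raise ConfigError(
            f"cannot sample {n_pos} positive pairs from {len(patched_ids)} "
            "patched proteins")
    if n_neg > 0 and not plain_ids:
        raise ConfigError("negative pairs require at least one patch-free protein")

    def sample_pairs(count, draw):
        seen, out = set(), []
        while len(out) < count:
            a, b = draw()
            if a == b:
                continue
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            out.append(key)
        return out

    pos_keys = sample_pairs(
        n_pos, lambda: rng.choice(patched_ids, size=2, replace=False))
    # a negative pair has at least one patch-free protein
    def draw_neg():
        a = plain_ids[rng.integers(len(plain_ids))]
        b = ids[rng.integers(n)]
        return a, b
    neg_keys = sample_pairs(n_neg, draw_neg)
    pairs = ([LabeledPair(str(a), str(b), 1) for a, b in pos_keys]
             + [LabeledPair(str(a), str(b), 0) for a, b in neg_keys])
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    return SyntheticWorld(config=config, structures=structures, pairs=pairs,
                          hotspot_truth=hotspot_truth)


# -- the separability certificate ---------------------------------------------

def oracle_has_patch(structure: ProteinStructure, patch_size: int,
                     hydrophobicity_cutoff: float = 0.9) -> bool:
    """Feature-threshold oracle: >= patch_size residues with normalized
    hydrophobicity above the cutoff."""
    table = default_property_table()
    col_idx = table.columns.index("hydrophobicity")
    count = sum(1 for r in structure.residues
                if table.row(r.code)[col_idx] > hydrophobicity_cutoff)
    return count >= patch_size


def oracle_labels(world: SyntheticWorld) -> np.ndarray:
    """Labels the feature oracle assigns to the world's pairs (certifies the
    planted rule is exactly separable: should match the true labels)."""
    has = {pid: oracle_has_patch(st, world.config.patch_size)
           for pid, st in world.structures.items()}
    return np.array([int(has[p.id_a] and has[p.id_b]) for p in world.pairs])


# -- export -------------------------------------------------------------------

def write_world(world: SyntheticWorld, out_dir) -> None:
    """One minimal PDB per protein + pair list + hotspot ground truth."""
    out_dir = Path(out_dir)
    (out_dir / "structures").mkdir(parents=True, exist_ok=True)
    for pid, st in sorted(world.structures.items()):
        (out_dir / "structures" / f"{pid}.pdb").write_text(write_pdb(st))
    write_pairs(world.pairs, out_dir / "pairs.tsv")
    with open(out_dir / "hotspots.tsv", "w") as fh:
        fh.write("protein_id\thotspot_residues\n")
        for pid in sorted(world.hotspot_truth):
            fh.write(f"{pid}\t{','.join(world.hotspot_truth[pid])}\n")
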