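"""Synthetic repertoires, ambient pools, corruptions and toy structures.

The generator emulates the study conditions end to end with known ground
truth:

- epitope-specific repertoires are proper CDR3B sequences built from a
  conserved C+"ASS"-like prefix and an "EQYF"-like suffix around uniformly
  random inner residues, with a short class motif implanted at fixed inner
  positions with a given probability (the epitope-specific signal);
- the ambient negative pool contains fully random proper sequences
  (C + uniform inner residues + F) with no conserved flank and no class
  motif, mimicking the diversity of a healthy-donor repertoire;
- properness corruption drops the leading C and/or appends a trailing G with
  per-epitope probabilities, emulating database-specific curation artifacts,
  and records the pre-corruption truth for round-trip checks;
- toy TCR-pMHC structures place a linear epitope under an arched CDR3B loop
  with analytically known residue distances, written as minimal PDB files.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
import pandas as pd

from .encoding import AMINO_ACIDS

PREFIXES = ["ASS", "ASR", "AIS"]
PREFIX_PROBS = [0.8, 0.1, 0.1]
SUFFIXES = ["EQYF", "EQFF", "SYQF"]
SUFFIX_PROBS = [0.8, 0.1, 0.1]


@dataclass(frozen=True)
class MotifSpec:
    """Ground-truth signal for one epitope class.

    ``implant_positions`` are 0-based CDR3B indices (inner positions only);
    the motif letters are written there with probability
    ``implant_probability`` per sequence.
    """

    epitope: str
    motif: str
    implant_positions: tuple
    implant_probability: float = 0.9
    class_size: int = 300
    lengths: tuple = (13, 14, 15)

    def __post_init__(self):
        if len(self.motif) != len(self.implant_positions):
            raise ValueError("motif and implant positions disagree in length")
        if not 0.0 <= self.implant_probability <= 1.0:
            raise ValueError("implant probability must be in [0, 1]")
        for L in self.lengths:
            for p in self.implant_positions:
                if not 1 <= p <= L - 2:
                    raise ValueError(
                        f"implant position {p} not inner for length {L}"
                    )


def default_motif_specs() -> list[MotifSpec]:
    """Three separable epitope classes at the default study conditions."""
    return [
        MotifSpec("GILGFVFTL", "TSS", (5, 6, 7)),
        MotifSpec("NLVPMVATV", "QPN", (5, 6, 7)),
        MotifSpec("ELAGIGILTV", "WDK", (5, 6, 7)),
    ]


def _random_inner(rng: np.random.Generator, n: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n))


def generate_repertoire(specs, rng_seed: int = 0,
                        with_motif_flag: bool = False) -> pd.DataFrame:
    """Generate positive (cdr3b, epitope) pairs per the motif specs.

    Sequences are unique within each class. With ``with_motif_flag`` the
    output carries a ``has_motif`` ground-truth column.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for spec in specs:
        seen: set[str] = set()
        while len(seen) < spec.class_size:
            L = int(rng.choice(spec.lengths))
            prefix = "C" + PREFIXES[rng.choice(len(PREFIXES), p=PREFIX_PROBS)]
            suffix = SUFFIXES[rng.choice(len(SUFFIXES), p=SUFFIX_PROBS)]
            inner_len = L - len(prefix) - len(suffix)
            if inner_len < 0:
                raise ValueError(f"length {L} too short for the flank model")
            seq = list(prefix + _random_inner(rng, inner_len) + suffix)
            has_motif = bool(rng.random() < spec.implant_probability)
            if has_motif:
                for p, letter in zip(spec.implant_positions, spec.motif):
                    seq[p] = letter
            seq = "".join(seq)
            if seq in seen:
                continue
            seen.add(seq)
            row = {"cdr3b": seq, "epitope": spec.epitope, "source": "synthetic"}
            if with_motif_flag:
                row["has_motif"] = has_motif
            rows.append(row)
    return pd.DataFrame(rows)


def generate_ambient_pool(n: int, rng_seed: int = 0,
                          lengths=(12, 13, 14, 15, 16),
                          exclude=None) -> list[str]:
    """Fully random proper sequences (C + uniform inner + F), unique and
    disjoint from ``exclude``."""
    rng = np.random.default_rng(rng_seed)
    exclude = set(exclude) if exclude is not None else set()
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < n:
        L = int(rng.choice(lengths))
        seq = "C" + _random_inner(rng, L - 2) + "F"
        if seq in seen or seq in exclude:
            continue
        seen.add(seq)
        pool.append(seq)
    return pool


def corrupt_properness(dataset: pd.DataFrame, drop_c_probs: dict,
                       append_g_probs: dict, rng_seed: int = 0) -> pd.DataFrame:
    """Apply epitope-specific curation artifacts to a proper dataset.

    Per record, the leading C is dropped with its epitope's probability and a
    trailing G appended with its epitope's probability (independently). The
    output keeps the pre-corruption string in ``original_cdr3b``.
    """
    rng = np.random.default_rng(rng_seed)
    out = dataset.copy().reset_index(drop=True)
    originals = list(out["cdr3b"])
    corrupted = []
    for seq, epitope in zip(originals, out["epitope"]):
        s = seq
        if rng.random() < drop_c_probs.get(epitope, 0.0):
            s = s[1:]
        if rng.random() < append_g_probs.get(epitope, 0.0):
            s = s + "G"
        corrupted.append(s)
    out["original_cdr3b"] = originals
    out["cdr3b"] = corrupted
    return out


def generate_toy_structure(path, epitope: str, cdr3b: str,
                           standoff: float = 5.0, curvature: float = 0.35,
                           spacing: float = 3.5, jitter: float = 0.0,
                           rng_seed: int = 0):
    """Write a minimal PDB of a linear epitope under an arched CDR3B loop.

    The epitope chain E lies along the x-axis with one C-alpha per residue at
    ``spacing`` A intervals; the CDR3B chain B arches over it with height
    ``standoff`` + ``curvature`` * (i - center)^2, so the central positions
    are the closest to the epitope. Returns the ground-truth residue distance
    matrix computed from the coordinates as written (3-decimal PDB
    precision).
    """
    rng = np.random.default_rng(rng_seed)
    Le, Lc = len(epitope), len(cdr3b)
    epi_xyz = np.zeros((Le, 3))
    epi_xyz[:, 0] = np.arange(Le) * spacing
    span = (Le - 1) * spacing
    cdr_xyz = np.zeros((Lc, 3))
    cdr_xyz[:, 0] = np.linspace(-spacing, span + spacing, Lc)
    center = (Lc - 1) / 2.0
    cdr_xyz[:, 2] = standoff + curvature * (np.arange(Lc) - center) ** 2
    if jitter > 0:
        cdr_xyz += rng.normal(0.0, jitter, cdr_xyz.shape)
    epi_xyz = np.round(epi_xyz, 3)
    cdr_xyz = np.round(cdr_xyz, 3)

    structure = gemmi.Structure()
    structure.name = "toy"
    model = gemmi.Model("1")
    aa3 = {a: gemmi.find_tabulated_residue(a).name
           for a in set(epitope + cdr3b)}
    for chain_name, seq, coords in (("E", epitope, epi_xyz),
                                    ("B", cdr3b, cdr_xyz)):
        chain = gemmi.Chain(chain_name)
        for i, (letter, xyz) in enumerate(zip(seq, coords), start=1):
            res = gemmi.Residue()
            res.name = aa3[letter]
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    structure.add_model(model)
    structure.resolution = 2.0
    structure.setup_entities()
    structure.write_pdb(str(path))

    diffs = cdr_xyz[:, None, :] - epi_xyz[None, :, :]
    truth = np.sqrt((diffs ** 2).sum(axis=2))
    return truth


def write_structure_manifest(path, entries) -> None:
    """Manifest TSV mapping structure files to chain/region definitions.

    ``entries``: iterables of dicts with keys structure_id, path,
    cdr3b_chain, cdr3b_start, cdr3b_end, epitope_chain, epitope, cdr3b.
    """
    pd.DataFrame(list(entries)).to_csv(path, sep="\t", index=False)
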