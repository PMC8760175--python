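"""Synthetic labeled SMILES datasets with a planted structure->label rule.

The generator emulates the statistical shape of a curated AIE/ACQ
literature set — 356 unique small organics, 134 AIE vs 222 ACQ — without
any download, by assembling molecules from a fragment library and labeling
them with a deterministic rotor rule that caricatures the restriction-of-
intramolecular-rotation picture of AIE:

    AIE  iff  (# aryl rotors >= rotor_threshold)
         and  (largest fused-ring system < fused_ring_block rings)

where an *aryl rotor* is a benzene or naphthalene unit attached to the rest
of the molecule by exactly one acyclic single bond (a freely rotating
phenyl/naphthyl propeller blade), and a large fused polycyclic system
stands in for the planar pi-stacking cores of classic ACQ fluorophores.
The rule is a caricature, not photophysics — but it is a function of
substructure counts that every fingerprint mode and the 2D descriptors can
see, so learnability of the planted labels is a meaningful end-to-end check.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from rdkit import Chem

from aievote.dataio import ACQ, AIE, Dataset, MoleculeRecord


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Study-shape parameters of the synthetic dataset."""

    n: int = 356
    n_positive: int = 134
    rotor_threshold: int = 3
    fused_ring_block: int = 3
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n:
            raise ValueError("need 0 <= n_positive <= n")
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must be a probability")
        if self.rotor_threshold < 1:
            raise ValueError("rotor_threshold must be >= 1")


@dataclasses.dataclass(frozen=True)
class FragmentLibrary:
    """SMILES building blocks for molecule assembly.

    ``cores`` are attachment scaffolds given as (smiles, slot atom indices);
    ``rotors`` are unsubstituted aryl units that remain rotors after a
    single attachment; ``planar_blocks`` are fused polycyclic aromatics;
    ``decorations`` are small substituents attached via their first atom.
    """

    cores: tuple[tuple[str, tuple[int, ...]], ...] = (
        ("C=C", (0, 0, 1, 1)),       # olefinic center (tetraarylethylene-like)
        ("N", (0, 0, 0)),            # triarylamine center
        ("C", (0, 0, 0, 0)),         # tetrahedral methane center
        ("C=Cc1ccccc1", (0, 0, 1)),  # styryl center
    )
    rotors: tuple[str, ...] = ("c1ccccc1", "c1ccc2ccccc2c1")
    planar_blocks: tuple[str, ...] = (
        "c1ccc2ccccc2c1",                    # naphthalene
        "c1ccc2cc3ccccc3cc2c1",              # anthracene
        "c1ccc2c(c1)ccc1ccccc12",            # phenanthrene
        "c1cc2ccc3cccc4ccc(c1)c2c34",        # pyrene
        "c1ccc2c(c1)ccc1c2ccc2ccccc21",      # chrysene
        "c1ccc2c(c1)c1cccc3cccc2c13",        # fluoranthene
        "c1ccc2c(c1)c1ccccc1c1ccccc21",      # triphenylene
    )
    decorations: tuple[str, ...] = (
        "C", "CC", "CCC", "C(C)C", "OC", "O", "F", "Cl", "C#N", "N(C)C",
    )

    def validate(self) -> None:
        for smi in (
            [s for s, _ in self.cores]
            + list(self.rotors)
            + list(self.planar_blocks)
            + list(self.decorations)
        ):
            if Chem.MolFromSmiles(smi) is None:
                raise ValueError(f"invalid library fragment: {smi!r}")


DEFAULT_LIBRARY = FragmentLibrary()


def _ring_systems(mol: Chem.Mol) -> list[dict]:
    """Fused ring systems: connected components of SSSR rings sharing a bond."""
    rings = [set(r) for r in mol.GetRingInfo().BondRings()]
    n = len(rings)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if rings[i] & rings[j]:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    systems = []
    for members in comps.values():
        bonds = set().union(*(rings[i] for i in members))
        atoms: set[int] = set()
        for b in bonds:
            bond = mol.GetBondWithIdx(b)
            atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        systems.append({"n_rings": len(members), "atoms": atoms})
    return systems


def _count_aryl_rotors(mol: Chem.Mol, systems: list[dict]) -> int:
    rotors = 0
    for system in systems:
        if system["n_rings"] > 2:
            continue
        atoms = system["atoms"]
        if not all(
            mol.GetAtomWithIdx(a).GetIsAromatic()
            and mol.GetAtomWithIdx(a).GetSymbol() == "C"
            for a in atoms
        ):
            continue
        external = [
            mol.GetBondBetweenAtoms(a, nb.GetIdx())
            for a in atoms
            for nb in mol.GetAtomWithIdx(a).GetNeighbors()
            if nb.GetIdx() not in atoms
        ]
        if (
            len(external) == 1
            and external[0].GetBondType() == Chem.BondType.SINGLE
            and not external[0].IsInRing()
        ):
            rotors += 1
    return rotors


def label_molecule(
    smiles: str, rotor_threshold: int = 3, fused_ring_block: int = 3
) -> str:
    """Apply the planted rotor rule to one molecule; deterministic."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    systems = _ring_systems(mol)
    rotors = _count_aryl_rotors(mol, systems)
    largest = max((s["n_rings"] for s in systems), default=0)
    is_aie = rotors >= rotor_threshold and largest < fused_ring_block
    return AIE if is_aie else ACQ


def _attach(mol: Chem.Mol, atom_idx: int, fragment_smiles: str) -> Chem.Mol | None:
    """Join a fragment to ``mol`` by a single bond; None on chemistry failure."""
    fragment = Chem.MolFromSmiles(fragment_smiles)
    combined = Chem.RWMol(Chem.CombineMols(mol, fragment))
    combined.AddBond(atom_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    out = combined.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _aromatic_ch_indices(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetIsAromatic() and a.GetTotalNumHs() > 0
    ]


def _propose_propeller(rng: np.random.Generator, lib: FragmentLibrary) -> str | None:
    """A rotor-rich candidate: core with several aryl blades, maybe decorated."""
    kind = rng.integers(0, len(lib.cores) + 1)
    if kind < len(lib.cores):
        smiles, slots = lib.cores[kind]
        mol = Chem.MolFromSmiles(smiles)
        n_aryl = int(rng.integers(min(3, len(slots)), len(slots) + 1))
        order = list(slots)
        for pos in order[:n_aryl]:
            mol = _attach(mol, pos, str(rng.choice(lib.rotors)))
            if mol is None:
                return None
        for pos in order[n_aryl:]:
            if rng.random() < 0.6:
                mol = _attach(mol, pos, str(rng.choice(lib.decorations)))
                if mol is None:
                    return None
    else:
        # polyphenyl benzene: 3-5 aryl blades on a benzene core
        mol = Chem.MolFromSmiles("c1ccccc1")
        n_aryl = int(rng.integers(3, 6))
        for _ in range(n_aryl):
            sites = _aromatic_ch_indices(mol)
            if not sites:
                break
            mol = _attach(mol, int(rng.choice(sites)), str(rng.choice(lib.rotors)))
            if mol is None:
                return None
        if rng.random() < 0.4:
            sites = _aromatic_ch_indices(mol)
            if sites:
                mol = _attach(mol, int(rng.choice(sites)), str(rng.choice(lib.decorations)))
                if mol is None:
                    return None
    return Chem.MolToSmiles(mol)


def _propose_planar(rng: np.random.Generator, lib: FragmentLibrary) -> str | None:
    """A fused-polycyclic candidate with a few small substituents."""
    mol = Chem.MolFromSmiles(str(rng.choice(lib.planar_blocks)))
    for _ in range(int(rng.integers(0, 4))):
        sites = _aromatic_ch_indices(mol)
        if not sites:
            break
        mol = _attach(mol, int(rng.choice(sites)), str(rng.choice(lib.decorations)))
        if mol is None:
            return None
    return Chem.MolToSmiles(mol)


def _propose_low_rotor(rng: np.random.Generator, lib: FragmentLibrary) -> str | None:
    """A small core with 0-2 aryl blades (below the rotor threshold)."""
    mol = Chem.MolFromSmiles(str(rng.choice(["c1ccccc1", "c1ccc2ccccc2c1", "C=C"])))
    for _ in range(int(rng.integers(0, 3))):
        sites = _aromatic_ch_indices(mol) or list(range(mol.GetNumAtoms()))
        mol = _attach(mol, int(rng.choice(sites)), str(rng.choice(lib.rotors)))
        if mol is None:
            return None
    for _ in range(int(rng.integers(0, 3))):
        sites = _aromatic_ch_indices(mol)
        if not sites:
            break
        mol = _attach(mol, int(rng.choice(sites)), str(rng.choice(lib.decorations)))
        if mol is None:
            return None
    return Chem.MolToSmiles(mol)


def apply_label_noise(
    labels: list[str], noise: float, rng: np.random.Generator
) -> list[str]:
    """Independently flip each AIE/ACQ label with probability ``noise``."""
    flip = rng.random(len(labels)) < noise
    return [
        (ACQ if lab == AIE else AIE) if f else lab for lab, f in zip(labels, flip)
    ]


def generate_dataset(
    config: GeneratorConfig | None = None,
    library: FragmentLibrary | None = None,
    max_attempts_per_record: int = 500,
) -> Dataset:
    """Generate a unique-SMILES dataset with exact class quotas before noise.

    Candidates are assembled from the fragment library, canonicalized,
    deduplicated, labeled by the planted rule and routed into the class
    quota still open (rejection sampling).  After the quotas are filled,
    each label is independently flipped with probability ``label_noise``.
    Deterministic under ``config.seed``.
    """
    config = config or GeneratorConfig()
    lib = library or DEFAULT_LIBRARY
    lib.validate()
    rng = np.random.default_rng(config.seed)
    need = {AIE: config.n_positive, ACQ: config.n - config.n_positive}
    seen: set[str] = set()
    accepted: list[tuple[str, str]] = []
    attempts = 0
    max_attempts = max_attempts_per_record * max(config.n, 1)
    while (need[AIE] > 0 or need[ACQ] > 0) and attempts < max_attempts:
        attempts += 1
        total_need = need[AIE] + need[ACQ]
        want_aie = rng.random() < need[AIE] / total_need
        if want_aie:
            smiles = _propose_propeller(rng, lib)
        elif rng.random() < 0.6:
            smiles = _propose_planar(rng, lib)
        else:
            smiles = _propose_low_rotor(rng, lib)
        if smiles is None or smiles in seen:
            continue
        label = label_molecule(smiles, config.rotor_threshold, config.fused_ring_block)
        if need[label] <= 0:
            continue
        seen.add(smiles)
        need[label] -= 1
        accepted.append((smiles, label))
    if need[AIE] > 0 or need[ACQ] > 0:
        raise RuntimeError(
            f"could not fill class quotas after {attempts} attempts; "
            f"still need {need} — enrich the fragment library"
        )
    labels = apply_label_noise([lab for _, lab in accepted], config.label_noise, rng)
    width = max(4, len(str(config.n)))
    records = [
        MoleculeRecord(f"synth-{i:0{width}d}", smiles, lab)
        for i, ((smiles, _), lab) in enumerate(zip(accepted, labels))
    ]
    return Dataset(records)
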