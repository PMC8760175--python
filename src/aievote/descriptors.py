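"""Registry of the default 108 quantitative descriptors.

The quantitative feature vector concatenates 20 composition-level (1D)
descriptors with 88 graph-level (2D) descriptors, all computed by RDKit.
Descriptor families that can return NaN on ordinary organics (partial-charge
extrema, BCUT2D eigenvalues) or overflow (Ipc) are deliberately excluded so
that the vector is finite for every valid molecule.  The list is
config-replaceable: any ordered subset of ``rdkit.Chem.Descriptors`` names
can be supplied instead.
"""

from __future__ import annotations

from rdkit.Chem import Descriptors

# Composition-level descriptors: atom/electron/bond tallies, mass, simple
# functional-group counts.  No graph topology beyond connectivity counts.
ONE_D_DESCRIPTORS: tuple[str, ...] = (
    "MolWt",
    "ExactMolWt",
    "HeavyAtomMolWt",
    "NumValenceElectrons",
    "NumRadicalElectrons",
    "HeavyAtomCount",
    "NumHeteroatoms",
    "NumHAcceptors",
    "NumHDonors",
    "NHOHCount",
    "NOCount",
    "NumRotatableBonds",
    "FractionCSP3",
    "fr_halogen",
    "fr_NH0",
    "fr_NH1",
    "fr_NH2",
    "fr_ether",
    "fr_ester",
    "fr_nitrile",
)

# Graph-level descriptors: connectivity chi/kappa indices, topological
# complexity, surface-area partitions, ring-system counts, E-state extrema.
TWO_D_DESCRIPTORS: tuple[str, ...] = (
    # connectivity chi family
    "Chi0", "Chi0n", "Chi0v", "Chi1", "Chi1n", "Chi1v",
    "Chi2n", "Chi2v", "Chi3n", "Chi3v", "Chi4n", "Chi4v",
    # shape kappa family and alpha correction
    "Kappa1", "Kappa2", "Kappa3", "HallKierAlpha",
    # topological complexity
    "BalabanJ", "BertzCT",
    # surface/lipophilicity scalars
    "TPSA", "LabuteASA", "MolLogP", "MolMR", "SPS",
    # ring-system census
    "RingCount", "NumAromaticRings", "NumAliphaticRings", "NumSaturatedRings",
    "NumAromaticCarbocycles", "NumAromaticHeterocycles",
    "NumAliphaticCarbocycles", "NumAliphaticHeterocycles",
    "NumSaturatedCarbocycles", "NumSaturatedHeterocycles",
    "fr_bicyclic", "fr_benzene",
    # electrotopological-state extrema
    "MaxEStateIndex", "MinEStateIndex", "MaxAbsEStateIndex", "MinAbsEStateIndex",
    # Crippen-logP-binned surface areas
    "SlogP_VSA1", "SlogP_VSA2", "SlogP_VSA3", "SlogP_VSA4", "SlogP_VSA5",
    "SlogP_VSA6", "SlogP_VSA7", "SlogP_VSA8", "SlogP_VSA9", "SlogP_VSA10",
    "SlogP_VSA11", "SlogP_VSA12",
    # molar-refractivity-binned surface areas
    "SMR_VSA1", "SMR_VSA2", "SMR_VSA3", "SMR_VSA4", "SMR_VSA5",
    "SMR_VSA6", "SMR_VSA7", "SMR_VSA8", "SMR_VSA9", "SMR_VSA10",
    # E-state-binned surface areas
    "EState_VSA1", "EState_VSA2", "EState_VSA3", "EState_VSA4", "EState_VSA5",
    "EState_VSA6", "EState_VSA7", "EState_VSA8", "EState_VSA9", "EState_VSA10",
    "EState_VSA11",
    # surface-area-binned E-state sums
    "VSA_EState1", "VSA_EState2", "VSA_EState3", "VSA_EState4", "VSA_EState5",
    "VSA_EState6", "VSA_EState7", "VSA_EState8", "VSA_EState9", "VSA_EState10",
    # fingerprint bit densities (Morgan radius 1-3)
    "FpDensityMorgan1", "FpDensityMorgan2", "FpDensityMorgan3",
    # aromatic substitution-pattern counts
    "fr_aryl_methyl", "fr_Ar_N", "fr_methoxy",
)

DEFAULT_DESCRIPTOR_NAMES: tuple[str, ...] = ONE_D_DESCRIPTORS + TWO_D_DESCRIPTORS

_REGISTRY = dict(Descriptors._descList)


def descriptor_function(name: str):
    """Return the RDKit function computing descriptor ``name``."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown RDKit descriptor: {name!r}") from None


def _check_registry() -> None:
    missing = [n for n in DEFAULT_DESCRIPTOR_NAMES if n not in _REGISTRY]
    if missing:
        raise RuntimeError(f"RDKit build lacks descriptors: {missing}")
    assert len(ONE_D_DESCRIPTORS) == 20
    assert len(TWO_D_DESCRIPTORS) == 88
    assert len(set(DEFAULT_DESCRIPTOR_NAMES)) == 108


_check_registry()
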