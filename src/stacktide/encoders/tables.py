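"""Property tables and group partitions backing the sequence encoders.

All tables are defined over the fixed alphabet ACDEFGHIKLMNPQRSTVWY and
versioned with the package; nothing is fetched at runtime. Values are
classical literature constants except for the large amino-acid-index panel,
which is a synthetic stand-in (see ``synthetic_aaindex_table``).
"""

from __future__ import annotations

import hashlib

import numpy as np

from stacktide.sequence_io import ALPHABET

AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}


def _vec(table: dict[str, float]) -> np.ndarray:
    return np.array([table[a] for a in ALPHABET], dtype=float)


# --- pseudo amino acid composition property triplet (Chou's convention) ---
# Hydrophobicity (Tanford-style consensus scale used in pseudo-AAC work)
HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}
# Hydrophilicity (Hopp-Woods)
HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}
# Side-chain mass (Da)
SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}


def paac_standardize(table: dict[str, float]) -> np.ndarray:
    """Chou's standardization: center on the 20-residue mean, scale by the
    population standard deviation over the 20 residues."""
    v = _vec(table)
    return (v - v.mean()) / np.sqrt(((v - v.mean()) ** 2).mean())


# --- composition/transition/distribution: 7 attributes x 3 groups ---
# The canonical three-way physicochemical partitions used by CTD-style
# descriptor toolkits.
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MPSTHY"),
}


# --- reduced amino acid alphabets -----------------------------------------
# Class partitions for the five reduced-sequence encoders. Each maps every
# one of the 20 residues to exactly one class; the n-gram schedule lives in
# the encoder module.
REDUCED_ALPHABETS: dict[str, tuple[str, ...]] = {
    # acidity: acidic / basic / polar-neutral / nonpolar
    "RSacid": ("DE", "HKR", "CGNQSTY", "AFILMPVW"),
    # charge: positive / negative / histidine / polar-uncharged / hydrophobic
    "RScharge": ("KR", "DE", "H", "CNQSTY", "AFGILMPVW"),
    # hydrophobicity pattern: strong / weak / amphipathic-polar / charged
    "RSDHP": ("CFILMVW", "AGPST", "HNQY", "DEKR"),
    # polarity: charged-polar / uncharged-polar / aliphatic / aromatic-sulfur
    "RSpolar": ("DEHKR", "CNQSTY", "AGILPV", "FMW"),
    # secondary-structure propensity: helix / sheet / turn / proline (breaker)
    "RSsecond": ("AEHKLMQR", "CFITVWY", "DGNS", "P"),
}


def reduced_map(scheme: str) -> dict[str, int]:
    """Residue -> class index for a reduced alphabet scheme."""
    groups = REDUCED_ALPHABETS[scheme]
    out: dict[str, int] = {}
    for ci, members in enumerate(groups):
        for a in members:
            out[a] = ci
    assert len(out) == 20, f"{scheme}: partition does not cover the alphabet"
    return out


# --- global physicochemical property panel (11 classical scales) ----------
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}
ISOELECTRIC_POINT = {
    "A": 6.00, "C": 5.07, "D": 2.77, "E": 3.22, "F": 5.48,
    "G": 5.97, "H": 7.59, "I": 6.02, "K": 9.74, "L": 5.98,
    "M": 5.74, "N": 5.41, "P": 6.30, "Q": 5.65, "R": 10.76,
    "S": 5.68, "T": 5.60, "V": 5.96, "W": 5.89, "Y": 5.66,
}
NET_CHARGE_PH7 = {a: 0.0 for a in ALPHABET} | {"K": 1.0, "R": 1.0, "H": 0.1, "D": -1.0, "E": -1.0}
GRANTHAM_POLARITY = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2,
    "G": 9.0, "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9,
    "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5, "R": 10.5,
    "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2,
}
# Chou-Fasman conformational propensities
HELIX_PROPENSITY = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13,
    "G": 0.57, "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21,
    "M": 1.45, "N": 0.67, "P": 0.57, "Q": 1.11, "R": 0.98,
    "S": 0.77, "T": 0.83, "V": 1.06, "W": 1.08, "Y": 0.69,
}
SHEET_PROPENSITY = {
    "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38,
    "G": 0.75, "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30,
    "M": 1.05, "N": 0.89, "P": 0.55, "Q": 1.10, "R": 0.93,
    "S": 0.75, "T": 1.19, "V": 1.70, "W": 1.37, "Y": 1.47,
}
TURN_PROPENSITY = {
    "A": 0.66, "C": 1.19, "D": 1.46, "E": 0.74, "F": 0.60,
    "G": 1.56, "H": 0.95, "I": 0.47, "K": 1.01, "L": 0.59,
    "M": 0.60, "N": 1.56, "P": 1.52, "Q": 0.98, "R": 0.95,
    "S": 1.43, "T": 0.96, "V": 0.50, "W": 0.96, "Y": 1.14,
}
AROMATICITY = {a: (1.0 if a in "FWY" else 0.0) for a in ALPHABET}

PCP_TABLE: dict[str, dict[str, float]] = {
    "hydropathy_kd": KYTE_DOOLITTLE,
    "hydrophilicity_hw": HYDROPHILICITY,
    "side_chain_mass": SIDE_CHAIN_MASS,
    "isoelectric_point": ISOELECTRIC_POINT,
    "net_charge_ph7": NET_CHARGE_PH7,
    "polarity_grantham": GRANTHAM_POLARITY,
    "helix_propensity": HELIX_PROPENSITY,
    "sheet_propensity": SHEET_PROPENSITY,
    "turn_propensity": TURN_PROPENSITY,
    "aromaticity": AROMATICITY,
    "hydrophobicity_consensus": HYDROPHOBICITY,
}
assert len(PCP_TABLE) == 11


N_AAI_PROPERTIES = 531
_AAI_SEED = 20230531  # fixed: the panel is part of the package, not of a run


def synthetic_aaindex_table() -> tuple[np.ndarray, list[str]]:
    """Deterministic SYNTHETIC 531-property amino-acid index panel.

    A stand-in for a curated amino-acid-index panel of 531 complete
    physicochemical scales: property values are drawn once from a fixed-seed
    generator and z-standardized per property, so each property is an
    arbitrary but reproducible 20-vector. The panel gives the encoder its
    full dimensionality and realistic value ranges; it does not carry real
    biochemical meaning. Returns (531 x 20 matrix, property names).
    """
    rng = np.random.default_rng(_AAI_SEED)
    m = rng.normal(size=(N_AAI_PROPERTIES, 20))
    m = (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, keepdims=True)
    names = [f"SYNAAI{i:04d}" for i in range(1, N_AAI_PROPERTIES + 1)]
    return m, names


def pcp_matrix(standardize: bool = True) -> tuple[np.ndarray, list[str]]:
    """11 x 20 matrix of the classical property panel, z-scored per property."""
    names = list(PCP_TABLE)
    m = np.stack([_vec(PCP_TABLE[n]) for n in names])
    if standardize:
        m = (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, keepdims=True)
    return m, names


def tables_fingerprint() -> str:
    """Stable hash of every encoder table; embedded in model archives so a
    predictor can refuse inputs encoded under different tables."""
    h = hashlib.sha256()
    for name, tab in sorted(PCP_TABLE.items()):
        h.update(name.encode())
        h.update(_vec(tab).tobytes())
    for scheme, groups in sorted(REDUCED_ALPHABETS.items()):
        h.update((scheme + "|".join(groups)).encode())
    for attr, groups in sorted(CTD_GROUPS.items()):
        h.update((attr + "|".join(groups)).encode())
    for tab in (HYDROPHOBICITY, HYDROPHILICITY, SIDE_CHAIN_MASS):
        h.update(_vec(tab).tobytes())
    aai, _ = synthetic_aaindex_table()
    h.update(aai.tobytes())
    return h.hexdigest()[:16]
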