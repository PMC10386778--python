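"""Twelve peptide feature encoders with fixed dimensional contracts.

Every encoder maps a validated peptide sequence to a fixed-length real
vector; the registry enumerates the full panel:

====================  ====  =====================================================
name                  dim   description
====================  ====  =====================================================
AAC                    20   amino acid composition
AAI                   531   means of a 531-scale amino-acid-index panel
APAAC                  22   amphiphilic pseudo amino acid composition (lambda=1)
CTD                   147   composition/transition/distribution, 7 attributes
DPC                   400   dipeptide composition
PCP                    11   means of 11 classical physicochemical scales
PAAC                   21   pseudo amino acid composition (lambda=1)
RSacid                 32   reduced alphabet (acidity), n-gram blocks
RScharge               50   reduced alphabet (charge), n-gram blocks
RSDHP                  32   reduced alphabet (hydrophobicity pattern)
RSpolar                32   reduced alphabet (polarity)
RSsecond               40   reduced alphabet (secondary structure)
====================  ====  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from stacktide.sequence_io import ALPHABET, PeptideDataset
from stacktide.encoders import tables
from stacktide.encoders.tables import (
    AA_INDEX,
    CTD_GROUPS,
    HYDROPHILICITY,
    HYDROPHOBICITY,
    SIDE_CHAIN_MASS,
    paac_standardize,
    pcp_matrix,
    reduced_map,
    synthetic_aaindex_table,
    tables_fingerprint,
)

__all__ = [
    "EncoderSpec", "FeatureMatrix", "encoder_registry", "get_encoder",
    "encode_dataset", "encode_aac", "encode_dpc", "encode_ctd",
    "encode_paac", "encode_apaac", "encode_property_mean", "encode_reduced",
    "tables_fingerprint",
]

ENCODER_NAMES = (
    "AAC", "AAI", "APAAC", "CTD", "DPC", "PCP",
    "PAAC", "RSacid", "RScharge", "RSDHP", "RSpolar", "RSsecond",
)


@dataclass(frozen=True)
class EncoderSpec:
    """A descriptor scheme: name, output dimension and parameters."""

    name: str
    dimension: int
    params: dict = field(default_factory=dict, compare=False)

    def encode(self, seq: str) -> np.ndarray:
        return get_encoder(self.name)(seq)

    def column_names(self) -> list[str]:
        return _COLUMN_NAMES[self.name]


@dataclass
class FeatureMatrix:
    """Numeric matrix produced by one encoder over a dataset."""

    encoder: EncoderSpec
    values: np.ndarray
    column_names: list[str]
    row_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names, index=self.row_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id")


# --------------------------------------------------------------------------
# composition encoders

def encode_aac(seq: str) -> np.ndarray:
    """Amino acid composition: residue frequencies in fixed alphabet order."""
    v = np.zeros(20)
    for a in seq:
        v[AA_INDEX[a]] += 1.0
    return v / len(seq)


def encode_dpc(seq: str) -> np.ndarray:
    """Dipeptide composition: frequencies of the 400 adjacent residue pairs."""
    v = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        v[AA_INDEX[a] * 20 + AA_INDEX[b]] += 1.0
    return v / (len(seq) - 1)


# --------------------------------------------------------------------------
# composition / transition / distribution

_CTD_ATTRS = list(CTD_GROUPS)
_CTD_MAPS = {attr: {a: gi for gi, grp in enumerate(groups) for a in grp}
             for attr, groups in CTD_GROUPS.items()}


def encode_ctd(seq: str) -> np.ndarray:
    """CTD descriptor over 7 three-group physicochemical partitions.

    Per attribute: 3 group composition fractions, 3 between-group transition
    frequencies, and per group 5 distribution points — the positions (as
    percent of sequence length) of the first occurrence and of the
    ceil(q * n_g)-th occurrence for q in {25%, 50%, 75%, 100%}. Groups absent
    from the sequence contribute zeros. 7 * (3 + 3 + 15) = 147 components.
    """
    L = len(seq)
    out = np.empty(147)
    pos = 0
    for attr in _CTD_ATTRS:
        gmap = _CTD_MAPS[attr]
        classes = [gmap[a] for a in seq]
        # composition
        counts = np.bincount(classes, minlength=3).astype(float)
        out[pos:pos + 3] = counts / L
        pos += 3
        # transitions between distinct groups, unordered pairs (0,1),(0,2),(1,2)
        t = np.zeros(3)
        for r, s in zip(classes, classes[1:]):
            if r != s:
                t[{frozenset((0, 1)): 0, frozenset((0, 2)): 1, frozenset((1, 2)): 2}[frozenset((r, s))]] += 1.0
        out[pos:pos + 3] = t / (L - 1)
        pos += 3
        # distribution
        for g in range(3):
            positions = [i + 1 for i, c in enumerate(classes) if c == g]
            if not positions:
                out[pos:pos + 5] = 0.0
            else:
                ng = len(positions)
                idxs = [1] + [int(np.ceil(q * ng)) for q in (0.25, 0.50, 0.75, 1.00)]
                out[pos:pos + 5] = [100.0 * positions[i - 1] / L for i in idxs]
            pos += 5
    return out


# --------------------------------------------------------------------------
# pseudo amino acid composition family

_H1 = paac_standardize(HYDROPHOBICITY)
_H2 = paac_standardize(HYDROPHILICITY)
_M = paac_standardize(SIDE_CHAIN_MASS)

DEFAULT_LAMBDA = 1
DEFAULT_WEIGHT = 0.05


def encode_paac(seq: str, lam: int = DEFAULT_LAMBDA, w: float = DEFAULT_WEIGHT) -> np.ndarray:
    """Pseudo amino acid composition: 20 composition terms plus ``lam``
    sequence-order correlation factors built from standardized
    hydrophobicity, hydrophilicity and side-chain mass.
    """
    L = len(seq)
    if L <= lam:
        raise ValueError(f"sequence length {L} must exceed lambda={lam}")
    idx = np.array([AA_INDEX[a] for a in seq])
    f = np.bincount(idx, minlength=20) / L
    thetas = []
    for k in range(1, lam + 1):
        a, b = idx[:-k], idx[k:]
        corr = ((_H1[a] - _H1[b]) ** 2 + (_H2[a] - _H2[b]) ** 2 + (_M[a] - _M[b]) ** 2) / 3.0
        thetas.append(corr.mean())
    theta = np.array(thetas)
    denom = f.sum() + w * theta.sum()
    return np.concatenate([f, w * theta]) / denom


def encode_apaac(seq: str, lam: int = DEFAULT_LAMBDA, w: float = DEFAULT_WEIGHT) -> np.ndarray:
    """Amphiphilic pseudo amino acid composition: the 2*lam correlation terms
    keep hydrophobicity and hydrophilicity separate (products, not squared
    differences), so even a homopolymer has nonzero sequence-order terms.
    """
    L = len(seq)
    if L <= lam:
        raise ValueError(f"sequence length {L} must exceed lambda={lam}")
    idx = np.array([AA_INDEX[a] for a in seq])
    f = np.bincount(idx, minlength=20) / L
    taus = []
    for k in range(1, lam + 1):
        a, b = idx[:-k], idx[k:]
        taus.append((_H1[a] * _H1[b]).mean())
        taus.append((_H2[a] * _H2[b]).mean())
    tau = np.array(taus)
    denom = f.sum() + w * tau.sum()
    return np.concatenate([f, w * tau]) / denom


# --------------------------------------------------------------------------
# property-mean encoders (AAI panel and classical PCP panel)

_AAI_MATRIX, _AAI_NAMES = synthetic_aaindex_table()
_PCP_MATRIX, _PCP_NAMES = pcp_matrix()


def encode_property_mean(seq: str, matrix: np.ndarray) -> np.ndarray:
    """Mean of per-residue (standardized) property values, one component per
    property row of ``matrix`` (n_properties x 20)."""
    idx = np.array([AA_INDEX[a] for a in seq])
    return matrix[:, idx].mean(axis=1)


def encode_aai(seq: str) -> np.ndarray:
    return encode_property_mean(seq, _AAI_MATRIX)


def encode_pcp(seq: str) -> np.ndarray:
    return encode_property_mean(seq, _PCP_MATRIX)


# --------------------------------------------------------------------------
# reduced-alphabet n-gram encoders

# Block schedule per scheme. Blocks: "di0" adjacent class dipeptides,
# "di1" one-gap class dipeptides, "uni_n"/"uni_c" class composition of the
# N-/C-terminal half. Dimensions: RSacid/RSDHP/RSpolar 2*4^2=32,
# RScharge 2*5^2=50, RSsecond 16+16+4+4=40.
RS_SCHEDULES: dict[str, tuple[str, ...]] = {
    "RSacid": ("di0", "di1"),
    "RScharge": ("di0", "di1"),
    "RSDHP": ("di0", "di1"),
    "RSpolar": ("di0", "di1"),
    "RSsecond": ("di0", "di1", "uni_n", "uni_c"),
}

_RS_MAPS = {scheme: reduced_map(scheme) for scheme in RS_SCHEDULES}
_RS_K = {scheme: len(tables.REDUCED_ALPHABETS[scheme]) for scheme in RS_SCHEDULES}


def _class_dipeptides(classes: list[int], k: int, gap: int) -> np.ndarray:
    v = np.zeros(k * k)
    n = len(classes) - gap - 1
    for i in range(n):
        v[classes[i] * k + classes[i + gap + 1]] += 1.0
    return v / n


def _class_composition(classes: list[int], k: int) -> np.ndarray:
    return np.bincount(classes, minlength=k).astype(float) / len(classes)


def encode_reduced(seq: str, scheme: str) -> np.ndarray:
    """Translate into the scheme's reduced alphabet, then concatenate the
    scheme's n-gram composition blocks; every block sums to 1."""
    if scheme not in RS_SCHEDULES:
        raise KeyError(f"unknown reduced scheme {scheme!r}")
    gmap, k = _RS_MAPS[scheme], _RS_K[scheme]
    classes = [gmap[a] for a in seq]
    half = len(classes) // 2
    blocks = []
    for block in RS_SCHEDULES[scheme]:
        if block == "di0":
            blocks.append(_class_dipeptides(classes, k, gap=0))
        elif block == "di1":
            blocks.append(_class_dipeptides(classes, k, gap=1))
        elif block == "uni_n":
            blocks.append(_class_composition(classes[:half], k))
        elif block == "uni_c":
            blocks.append(_class_composition(classes[half:], k))
        else:  # pragma: no cover
            raise ValueError(f"unknown block {block!r}")
    return np.concatenate(blocks)


# --------------------------------------------------------------------------
# registry

def _dipeptide_names() -> list[str]:
    return [a + b for a in ALPHABET for b in ALPHABET]


def _ctd_names() -> list[str]:
    names = []
    for attr in _CTD_ATTRS:
        names += [f"{attr}.C{g}" for g in (1, 2, 3)]
        names += [f"{attr}.T{p}" for p in ("12", "13", "23")]
        for g in (1, 2, 3):
            names += [f"{attr}.D{g}.{q}" for q in ("first", "p25", "p50", "p75", "last")]
    return names


def _rs_names(scheme: str) -> list[str]:
    k = _RS_K[scheme]
    names = []
    for block in RS_SCHEDULES[scheme]:
        if block in ("di0", "di1"):
            names += [f"{scheme}.{block}.{i}{j}" for i in range(k) for j in range(k)]
        else:
            names += [f"{scheme}.{block}.{i}" for i in range(k)]
    return names


_COLUMN_NAMES: dict[str, list[str]] = {
    "AAC": list(ALPHABET),
    "AAI": _AAI_NAMES,
    "APAAC": [f"f.{a}" for a in ALPHABET] + ["tau1.hphob", "tau1.hphil"],
    "CTD": _ctd_names(),
    "DPC": _dipeptide_names(),
    "PCP": _PCP_NAMES,
    "PAAC": [f"f.{a}" for a in ALPHABET] + ["theta1"],
    **{s: _rs_names(s) for s in RS_SCHEDULES},
}

_ENCODER_FUNCS: dict[str, Callable[[str], np.ndarray]] = {
    "AAC": encode_aac,
    "AAI": encode_aai,
    "APAAC": encode_apaac,
    "CTD": encode_ctd,
    "DPC": encode_dpc,
    "PCP": encode_pcp,
    "PAAC": encode_paac,
    **{s: (lambda seq, _s=s: encode_reduced(seq, _s)) for s in RS_SCHEDULES},
}

_DIMENSIONS = {
    "AAC": 20, "AAI": 531, "APAAC": 22, "CTD": 147, "DPC": 400, "PCP": 11,
    "PAAC": 21, "RSacid": 32, "RScharge": 50, "RSDHP": 32, "RSpolar": 32,
    "RSsecond": 40,
}

_PARAMS = {
    "APAAC": {"lambda": DEFAULT_LAMBDA, "w": DEFAULT_WEIGHT},
    "PAAC": {"lambda": DEFAULT_LAMBDA, "w": DEFAULT_WEIGHT},
    **{s: {"groups": tables.REDUCED_ALPHABETS[s], "schedule": RS_SCHEDULES[s]}
       for s in RS_SCHEDULES},
}


def get_encoder(name: str) -> Callable[[str], np.ndarray]:
    try:
        return _ENCODER_FUNCS[name]
    except KeyError:
        raise KeyError(f"unknown encoder {name!r}; choose from {ENCODER_NAMES}") from None


def encoder_registry() -> list[EncoderSpec]:
    """The full panel of 12 encoder specs, in canonical order."""
    return [EncoderSpec(name=n, dimension=_DIMENSIONS[n], params=_PARAMS.get(n, {}))
            for n in ENCODER_NAMES]


def encode_dataset(ds: PeptideDataset, spec: EncoderSpec) -> FeatureMatrix:
    """Encode every peptide of a dataset; row order follows the dataset."""
    func = get_encoder(spec.name)
    rows = np.empty((len(ds), spec.dimension))
    for i, p in enumerate(ds.peptides):
        try:
            rows[i] = func(p.sequence)
        except Exception as exc:
            raise ValueError(f"encoding {spec.name} failed for peptide {p.id!r}: {exc}") from exc
    return FeatureMatrix(
        encoder=spec,
        values=rows,
        column_names=spec.column_names(),
        row_ids=[p.id for p in ds.peptides],
    )
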