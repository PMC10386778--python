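"""Synthetic labeled peptide data with controllable class signal.

The generator draws each peptide residue-wise i.i.d. from a
class-conditional residue distribution, optionally inserting a short motif
into positives, so every pipeline stage can be exercised without external
downloads. Positives tilt probability mass toward a fixed enriched residue
set (hydrophobic + basic: F, I, L, V, K, R) by a log-multiplier delta;
``effect`` maps to delta = 0 (none), 0.4 (weak) or 1.2 (strong). A "strong"
dataset of a few hundred peptides carries enough compositional signal for
a well-built classifier to exceed 0.9 AUC, while "none" produces
exchangeable classes for permutation-null checks.

This is deliberately not a model of MHC-I binding or of real tumor T-cell
antigen statistics; it provides detectable compositional signal, nothing
more. All randomness flows through one numpy default_rng (PCG64) seed, so
output is platform-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from stacktide.sequence_io import ALPHABET, Peptide, PeptideDataset, deduplicate

ENRICHED_RESIDUES = "FILVKR"
EFFECT_DELTA = {"none": 0.0, "weak": 0.4, "strong": 1.2}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (8, 30)
    effect: str = "strong"
    motif: str | None = None
    motif_prob: float = 0.8  # insertion probability per positive, if motif set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < 5:
            raise ValueError("minimum peptide length is 5")
        if self.effect not in EFFECT_DELTA:
            raise ValueError(f"effect must be one of {sorted(EFFECT_DELTA)}")


def class_distributions(effect: str) -> tuple[np.ndarray, np.ndarray]:
    """(P+, P-) residue distributions over the fixed 20-letter alphabet.

    The negative class is uniform; positives multiply the enriched residues
    by exp(delta) and renormalize. effect = "none" gives identical classes.
    """
    p_neg = np.full(20, 1 / 20)
    if EFFECT_DELTA[effect] == 0.0:
        return p_neg.copy(), p_neg
    tilt = np.array([EFFECT_DELTA[effect] if a in ENRICHED_RESIDUES else 0.0
                     for a in ALPHABET])
    p_pos = p_neg * np.exp(tilt)
    return p_pos / p_pos.sum(), p_neg


def _draw(rng: np.random.Generator, p: np.ndarray, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(ALPHABET), size=length, p=p))


def generate(cfg: SyntheticConfig) -> PeptideDataset:
    """Generate a deduplicated labeled dataset under ``cfg``.

    Duplicate draws are retried a bounded number of times; an infeasibly
    small sequence space raises instead of looping forever.
    """
    rng = np.random.default_rng(cfg.seed)
    p_pos, p_neg = class_distributions(cfg.effect)
    lo, hi = cfg.length_range
    peptides: list[Peptide] = []
    labels: list[int] = []
    seen: set[str] = set()
    for label, n, p in ((1, cfg.n_pos, p_pos), (0, cfg.n_neg, p_neg)):
        made = 0
        attempts = 0
        max_attempts = 50 * n + 1000
        while made < n:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not draw {n} unique length-[{lo},{hi}] sequences; "
                    "sequence space too small for deduplication")
            seq = _draw(rng, p, lo, hi)
            if label == 1 and cfg.motif and rng.random() < cfg.motif_prob:
                pos = int(rng.integers(0, len(seq) - len(cfg.motif) + 1))
                seq = seq[:pos] + cfg.motif + seq[pos + len(cfg.motif):]
            if seq in seen:
                continue
            seen.add(seq)
            cls = "pos" if label else "neg"
            peptides.append(Peptide(id=f"{cls}{made + 1:05d}", sequence=seq))
            labels.append(label)
            made += 1
    ds = PeptideDataset(peptides=peptides, labels=labels,
                        name=f"synthetic-{cfg.effect}-seed{cfg.seed}")
    return deduplicate(ds)


def planted_apf(n: int, signal_cols, seed: int = 0, n_cols: int = 156,
                noise_sd: float = 0.0):
    """Planted probabilistic-feature fixture for selection tests.

    Builds an n x n_cols matrix whose ``signal_cols`` equal the balanced
    0/1 label plus optional Gaussian noise (clipped to [0, 1]); every other
    column is label-independent uniform noise. Returns
    (ProbFeatureMatrix-like values, columns, labels) packed as
    (ProbFeatureMatrix, y).
    """
    from stacktide.meta_features import ProbFeatureMatrix

    signal_cols = list(signal_cols)
    if any(c >= n_cols for c in signal_cols):
        raise ValueError("signal column index out of range")
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    y = rng.permutation(y)
    values = rng.uniform(0.0, 1.0, size=(n, n_cols))
    for c in signal_cols:
        col = y.astype(float)
        if noise_sd > 0:
            col = col + rng.normal(0.0, noise_sd, size=n)
        values[:, c] = np.clip(col, 0.0, 1.0)
    columns = [f"pf{i:03d}" for i in range(n_cols)]
    return ProbFeatureMatrix(values=values, columns=columns, origin="out_of_fold"), y
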