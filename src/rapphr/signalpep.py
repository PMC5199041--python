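"""Position-weight-matrix scoring of Sec-type secretion signal peptides.

Phr propeptides carry an N-terminal secretion signal with the classical
tripartite architecture: a short positively charged n-region, a hydrophobic
h-region, and a small-residue c-region preceding the mature peptide. The
scorer is a fixed-anchor position weight matrix over the first 30 residues,
normalized so that the matrix consensus scores exactly 1.0 and scores always
lie in [0, 1]. Residues beyond position 45 can never influence the score
(only the first 30 are read).

The default acceptance threshold used downstream is 0.3.
"""

from __future__ import annotations

import numpy as np

from ._util import UndefinedScoreError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

PWM_LENGTH = 30
SCORE_WINDOW_END = 45  # contract: residues at index >= 45 never affect the score


def _row(base: float, **high: float) -> np.ndarray:
    w = np.full(len(AMINO_ACIDS), base)
    for aa, v in high.items():
        w[_AA_INDEX[aa]] = v
    return w


def _default_weights() -> np.ndarray:
    rows = []
    # position 0: initiator methionine (GTG/TTG starts translate V/L)
    rows.append(_row(0.005, M=1.0, V=0.4, L=0.4))
    # positions 1-4: n-region, positively charged
    for _ in range(4):
        rows.append(_row(0.005, K=1.0, R=0.55, H=0.2))
    # positions 5-19: h-region, hydrophobic core
    for _ in range(15):
        rows.append(_row(0.005, L=1.0, I=0.45, V=0.4, F=0.35, A=0.3, M=0.3))
    # positions 20-24: c-region, small residues near the cleavage site
    for _ in range(5):
        rows.append(_row(0.005, A=1.0, S=0.5, G=0.4, T=0.35))
    # positions 25-29: early mature region, mildly polar
    for _ in range(5):
        rows.append(_row(0.005, S=1.0, A=0.5, T=0.4, N=0.35, Q=0.3, E=0.3, K=0.3))
    return np.vstack(rows)


class SignalPeptidePWM:
    """Fixed-anchor PWM scorer for N-terminal secretion signals.

    Parameters
    ----------
    weights
        Array of shape (positions, 20) with per-position residue weights in
        (0, 1]; each row's maximum defines the consensus residue.
    """

    def __init__(self, weights: np.ndarray | None = None):
        self.weights = _default_weights() if weights is None else np.asarray(weights, float)
        if self.weights.ndim != 2 or self.weights.shape[1] != len(AMINO_ACIDS):
            raise ValueError("weights must have shape (positions, 20)")
        if self.weights.shape[0] > SCORE_WINDOW_END:
            raise ValueError(f"PWM may not read beyond position {SCORE_WINDOW_END}")
        self._row_max = self.weights.max(axis=1)

    def __len__(self) -> int:
        return self.weights.shape[0]

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.weights.argmax(axis=1))

    def score(self, protein: str) -> float:
        """Score in [0, 1]; the consensus N-terminus scores 1.0.

        Unknown residues (X and similar) contribute 0 at their position.
        Proteins shorter than 15 residues have no defined score.
        """
        if len(protein) < 15:
            raise UndefinedScoreError("signal score undefined for proteins shorter than 15 aa")
        n = min(len(protein), len(self))
        num = 0.0
        for pos in range(n):
            idx = _AA_INDEX.get(protein[pos])
            if idx is not None:
                num += self.weights[pos, idx]
        return float(num / self._row_max[:n].sum())

    def sample(self, rng: np.random.Generator, min_weight: float = 0.3) -> str:
        """Draw a plausible signal region: per position, residues with weight
        >= ``min_weight`` sampled proportionally to their weight."""
        out = []
        for pos in range(len(self)):
            w = self.weights[pos].copy()
            w[w < min_weight] = 0.0
            out.append(AMINO_ACIDS[rng.choice(len(w), p=w / w.sum())])
        return "".join(out)


DEFAULT_PWM = SignalPeptidePWM()


def signal_peptide_score(protein: str, pwm: SignalPeptidePWM = DEFAULT_PWM) -> float:
    """Module-level convenience wrapper around :meth:`SignalPeptidePWM.score`."""
    return pwm.score(protein)
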