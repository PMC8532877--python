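"""ORF prediction, coding-potential scoring and lncRNA filtering.

Transcripts reaching this stage are orientation-resolved (the FLNC
primers fix the strand), so ORFs are scanned in the three forward frames
only.  Coding potential combines the Fickett TESTCODE statistic with ORF
coverage and length through a logistic model trained on synthetic
coding/non-coding transcripts; its weights ship with the package so the
probability is deterministic.  The lncRNA filter is conjunctive: length
>= 200 nt AND coding probability <= 0.5 AND no protein-database hit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class ORF:
    """An open reading frame in transcript coordinates (0-based, half-open).

    ``end`` points one past the stop codon for complete / 5'-partial ORFs
    and to the scan end otherwise.  ``aa_length`` excludes the stop.
    """

    parent_id: str
    frame: int                  # 0, 1, 2
    start: int
    end: int
    aa_length: int
    completeness: str           # complete | 5prime_partial | 3prime_partial | internal


@dataclass
class CodingAssessment:
    isoform_id: str
    length: int
    coding_probability: float
    protein_db_hit: bool
    is_lncRNA: bool


# ------------------------------------------------------------------- ORFs

def find_orfs(sequence: str, parent_id: str = "", min_aa: int = 100) -> list[ORF]:
    """All qualifying ORFs in the three forward frames.

    Every ATG opens a candidate that runs to the first in-frame stop
    (complete) or the sequence end (3'-partial).  Each frame's leading
    open stretch — from the frame start to the first stop with no
    upstream ATG constraint — is additionally reported as 5'-partial
    (or internal when it never meets a stop).  ORFs under ``min_aa``
    amino acids are dropped.
    """
    seq = sequence.upper()
    n = len(seq)
    out: list[ORF] = []
    for frame in range(3):
        stops = [i for i in range(frame, n - 2, 3) if seq[i:i + 3] in STOP_CODONS]
        # leading open stretch without requiring ATG
        first_stop = stops[0] if stops else None
        lead_end = first_stop + 3 if first_stop is not None else n - (n - frame) % 3
        if not seq[frame:lead_end].startswith("ATG"):
            aa = (lead_end - frame) // 3 - (1 if first_stop is not None else 0)
            comp = "5prime_partial" if first_stop is not None else "internal"
            if aa >= min_aa:
                out.append(ORF(parent_id, frame, frame, lead_end, aa, comp))
        for i in range(frame, n - 2, 3):
            if seq[i:i + 3] != "ATG":
                continue
            stop = next((s for s in stops if s >= i), None)
            if stop is not None:
                aa = (stop - i) // 3
                if aa >= min_aa:
                    out.append(ORF(parent_id, frame, i, stop + 3, aa, "complete"))
            else:
                end = n - (n - i) % 3
                aa = (end - i) // 3
                if aa >= min_aa:
                    out.append(ORF(parent_id, frame, i, end, aa, "3prime_partial"))
    return out


def longest_orf(sequence: str, parent_id: str = "") -> ORF | None:
    orfs = find_orfs(sequence, parent_id, min_aa=1)
    return max(orfs, key=lambda o: (o.aa_length, -o.start)) if orfs else None


# ------------------------------------------------------------ Fickett

# TESTCODE lookup tables (Fickett 1982): probability-of-coding values per
# base for binned position-asymmetry and composition statistics, with the
# per-base discriminative weights.
_POSITION_PROB = {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.66, 0.60, 0.46, 0.35],
    "T": [0.51, 0.60, 0.69, 0.64, 0.53, 0.54, 0.44, 0.51, 0.40, 0.28],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
_CONTENT_PROB = {
    "A": [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19],
    "C": [0.50, 0.63, 0.59, 0.50, 0.41, 0.31, 0.33, 0.29, 0.24, 0.17],
    "G": [0.21, 0.40, 0.47, 0.50, 0.52, 0.60, 0.57, 0.52, 0.30, 0.17],
    "T": [0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.34, 0.20, 0.09, 0.09],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]

FICKETT_MIN = sum(min(_POSITION_PROB[b]) * _POSITION_WEIGHT[b]
                  + min(_CONTENT_PROB[b]) * _CONTENT_WEIGHT[b] for b in "ACGT")
FICKETT_MAX = sum(max(_POSITION_PROB[b]) * _POSITION_WEIGHT[b]
                  + max(_CONTENT_PROB[b]) * _CONTENT_WEIGHT[b] for b in "ACGT")


def _lookup(value: float, para: list[float], probs: list[float]) -> float:
    for threshold, prob in zip(para, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(sequence: str) -> float:
    """TESTCODE statistic from base position asymmetry and composition.

    Deterministic; higher values indicate protein-coding character.  The
    attainable range is [FICKETT_MIN, FICKETT_MAX] ≈ [0.43, 1.02].
    Requires at least 200 nt, the resolution the lookup tables were
    calibrated for.
    """
    seq = sequence.upper()
    if len(seq) < 200:
        raise ValueError("fickett_score requires a sequence of >= 200 nt")
    score = 0.0
    for base in "ACGT":
        counts = [seq[off::3].count(base) for off in range(3)]
        position = max(counts) / (min(counts) + 1)
        content = sum(counts) / len(seq)
        score += _lookup(position, _POSITION_PARA, _POSITION_PROB[base]) \
            * _POSITION_WEIGHT[base]
        score += _lookup(content, _CONTENT_PARA, _CONTENT_PROB[base]) \
            * _CONTENT_WEIGHT[base]
    return score


# --------------------------------------------------- logistic coding model

@dataclass
class CodingModel:
    """Logistic combination of ORF coverage, ORF length and Fickett score."""

    intercept: float | None = None
    coef: tuple[float, float, float] | None = None  # coverage, log10 length, fickett

    @property
    def trained(self) -> bool:
        return self.intercept is not None and self.coef is not None

    def features(self, sequence: str) -> np.ndarray:
        orf = longest_orf(sequence)
        orf_nt = 3 * orf.aa_length if orf else 0
        coverage = orf_nt / len(sequence) if sequence else 0.0
        return np.array([coverage, math.log10(orf_nt + 1), fickett_score(sequence)])

    def predict(self, sequence: str) -> float:
        if not self.trained:
            raise RuntimeError("coding model is untrained; load or fit weights first")
        z = self.intercept + float(np.dot(self.coef, self.features(sequence)))
        return 1.0 / (1.0 + math.exp(-z))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"intercept": self.intercept, "coef": list(self.coef)}, fh)

    @classmethod
    def load(cls, path=None) -> "CodingModel":
        """Load weights from a JSON file (default: the packaged weights)."""
        if path is None:
            ref = resources.files("capriseq.data") / "coding_model.json"
            payload = json.loads(ref.read_text())
        else:
            with open(path) as fh:
                payload = json.load(fh)
        return cls(intercept=payload["intercept"], coef=tuple(payload["coef"]))


def synthetic_training_set(n_per_class: int = 300, seed: int = 2024,
                           length_range: tuple[int, int] = (300, 2400)
                           ) -> tuple[list[str], np.ndarray]:
    """Labeled coding / non-coding transcripts for model fitting.

    Coding examples are a long ATG-initiated codon run (no in-frame
    stops, codon usage biased away from uniformity) between short UTRs;
    non-coding examples are the base-shuffled versions, which destroys
    both the reading frame and the periodic composition signal.
    """
    rng = np.random.default_rng(seed)
    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
              if a + b + c not in STOP_CODONS]
    weights = rng.dirichlet(np.ones(len(codons)) * 0.5)
    seqs: list[str] = []
    labels: list[int] = []
    for _ in range(n_per_class):
        total = int(rng.integers(*length_range))
        utr5 = int(rng.integers(10, 60))
        n_codons = max((total - utr5 - 50) // 3, 110)
        body = "ATG" + "".join(rng.choice(codons, size=n_codons, p=weights)) \
            + rng.choice(("TAA", "TAG", "TGA"))
        utr = "".join(rng.choice(list("ACGT"), size=utr5))
        utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 60))))
        coding = utr + body + utr3
        seqs.append(coding)
        labels.append(1)
        shuffled = list(coding)
        rng.shuffle(shuffled)
        seqs.append("".join(shuffled))
        labels.append(0)
    return seqs, np.asarray(labels)


def train_coding_model(n_per_class: int = 300, seed: int = 2024) -> CodingModel:
    """Fit the logistic weights on the synthetic training set."""
    from sklearn.linear_model import LogisticRegression

    seqs, y = synthetic_training_set(n_per_class, seed)
    probe = CodingModel(0.0, (0.0, 0.0, 0.0))
    X = np.array([probe.features(s) for s in seqs])
    clf = LogisticRegression(max_iter=2000)
    clf.fit(X, y)
    return CodingModel(float(clf.intercept_[0]), tuple(map(float, clf.coef_[0])))


def coding_probability(sequence: str, model: CodingModel) -> float:
    """Probability in [0, 1] that a transcript is protein-coding."""
    return model.predict(sequence)


# -------------------------------------------------------------- lncRNA

def classify_lncrna(length: int, coding_prob: float,
                    protein_db_hit: bool,
                    min_length: int = 200,
                    max_coding_probability: float = 0.5) -> bool:
    """Conjunctive lncRNA filter.

    A transcript is a lncRNA only when it is at least ``min_length`` nt,
    its coding probability is at or below ``max_coding_probability``, and
    it has no protein-database hit.  Raising the coding probability can
    therefore never turn a non-lncRNA into one.
    """
    return (length >= min_length
            and coding_prob <= max_coding_probability
            and not protein_db_hit)


def assess(isoform_id: str, sequence: str, protein_db_hit: bool,
           model: CodingModel) -> CodingAssessment:
    prob = model.predict(sequence) if len(sequence) >= 200 else 1.0
    return CodingAssessment(
        isoform_id=isoform_id, length=len(sequence),
        coding_probability=prob, protein_db_hit=protein_db_hit,
        is_lncRNA=classify_lncrna(len(sequence), prob, protein_db_hit))
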