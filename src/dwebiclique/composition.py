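"""Residue and residue-pair composition of mined hot-spot patterns.

For each interaction class, patterns contribute their residue multisets
(and all cross-side residue-type pairs) to a 20-component and a
210-component percent profile; profiles are compared to the Swiss-Prot
release 55.0 background composition to pick out:

* idR  — interaction-dominated residues: top-k (default 7) by frequency;
* ipR  — interaction-preferred residues: frequency ratio over background
  strictly above 1.05 (anti-ipR: strictly below 0.8);
* idRP — top-k residue pairs by frequency (default 10);
* ipRP — pairs whose frequency ratio r over the independence expectation
  (2 P_i P_j off-diagonal, P_i^2 diagonal) satisfies ln(r + 1) > 1.05.

Profiles of two classes are compared with the Euclidean distance Δf of
percent compositions and the Pearson correlation CC of ratio vectors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .biclique import SupportRecord

#: Alphabetical 3-letter codes: canonical axis of all 20-vectors.
AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: The 210 unordered residue-type pairs, alphabetical, diagonal included.
PAIRS: Tuple[Tuple[str, str], ...] = tuple(
    (AA3[i], AA3[j]) for i in range(20) for j in range(i, 20)
)

IPR_HI = 1.05      # ipR frequency-ratio threshold (strict >)
IPR_LO = 0.8       # anti-ipR threshold (strict <)
IPRP_LOG = 1.05    # ipRP threshold on ln(ratio + 1) (strict >)
IDR_K = 7
IDRP_K = 10

WEIGHTINGS = ("per_supporting_interaction", "per_pattern")


class UndefinedProfileError(ValueError):
    """No residues/pairs available to build a profile."""


@dataclass
class BackgroundComposition:
    """Background residue percentages and derived pair expectations."""

    percent: pd.Series  # indexed by AA3, sums to ~100

    @classmethod
    def swissprot55(cls) -> "BackgroundComposition":
        return _packaged_background()

    @property
    def fractions(self) -> pd.Series:
        return self.percent / self.percent.sum()

    def pair_expectation(self) -> pd.Series:
        """Multinomial independence expectation over the 210 unordered pairs:
        2 P_i P_j for i != j, P_i^2 on the diagonal; sums to 1."""
        p = self.fractions
        vals = {}
        for a, b in PAIRS:
            vals[(a, b)] = p[a] * p[b] * (2.0 if a != b else 1.0)
        return pd.Series(vals)


@lru_cache(maxsize=None)
def _packaged_background() -> BackgroundComposition:
    with resources.files("dwebiclique.data").joinpath(
        "swissprot55_background.json"
    ).open() as fh:
        raw = json.load(fh)["percent"]
    return BackgroundComposition(percent=pd.Series(raw).reindex(list(AA3)))


def _pattern_weight(rec: SupportRecord, class_label: str, weighting: str) -> int:
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    sup = rec.support_by_class.get(class_label, 0)
    if sup == 0:
        return 0
    return sup if weighting == "per_supporting_interaction" else 1


def residue_frequencies(
    records: Iterable[SupportRecord],
    class_label: str,
    weighting: str = "per_supporting_interaction",
) -> pd.Series:
    """Percent frequency of the 20 residue types in a class's patterns.

    With the default weighting each pattern contributes its full residue
    multiset once per supporting interaction of the class; ``per_pattern``
    counts each pattern once.
    """
    counts = pd.Series(0.0, index=list(AA3))
    for rec in records:
        w = _pattern_weight(rec, class_label, weighting)
        if w == 0:
            continue
        for t in rec.pattern.small_side + rec.pattern.large_side:
            counts[t] += w
    total = counts.sum()
    if total == 0:
        raise UndefinedProfileError(f"no residues for class {class_label!r}")
    return 100.0 * counts / total


def pair_frequencies(
    records: Iterable[SupportRecord],
    class_label: str,
    weighting: str = "per_supporting_interaction",
) -> pd.Series:
    """Percent frequency of the 210 unordered cross-side residue-type pairs.

    Each pattern contributes all |side1| x |side2| cross pairs (types
    unordered) with the same weighting as :func:`residue_frequencies`.
    """
    counts = pd.Series(0.0, index=pd.MultiIndex.from_tuples(PAIRS))
    for rec in records:
        w = _pattern_weight(rec, class_label, weighting)
        if w == 0:
            continue
        for a in rec.pattern.small_side:
            for b in rec.pattern.large_side:
                key = (a, b) if a <= b else (b, a)
                counts[key] += w
    total = counts.sum()
    if total == 0:
        raise UndefinedProfileError(f"no residue pairs for class {class_label!r}")
    return 100.0 * counts / total


def frequency_ratio(freq: pd.Series, background: BackgroundComposition) -> pd.Series:
    """Elementwise ratio of a percent profile over the background percents."""
    return freq / background.percent.reindex(freq.index)


def select_idR(freq: pd.Series, k: int = IDR_K) -> List[str]:
    """Top-k residues by frequency, descending; ties alphabetical."""
    if not 1 <= k <= len(freq):
        raise ValueError("k out of range")
    order = sorted(freq.index, key=lambda t: (-freq[t], t))
    return order[:k]


def select_ipR_antiipR(
    ratios: pd.Series, hi: float = IPR_HI, lo: float = IPR_LO
) -> Tuple[Set[str], Set[str]]:
    """ipR: ratio strictly above ``hi``; anti-ipR: strictly below ``lo``."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    ipr = {t for t in ratios.index if ratios[t] > hi}
    anti = {t for t in ratios.index if ratios[t] < lo}
    return ipr, anti


def pair_ratio_and_ipRP(
    pair_freq: pd.Series,
    background: BackgroundComposition,
    log_threshold: float = IPRP_LOG,
) -> Tuple[pd.Series, Set[Tuple[str, str]]]:
    """Pair frequency ratios over the independence expectation, and the
    ipRP selection: pairs with ln(ratio + 1) strictly above ``log_threshold``
    (equivalently ratio > e^threshold - 1)."""
    expectation = background.pair_expectation().reindex(pair_freq.index)
    observed = pair_freq / 100.0  # fractions, comparable to the expectation
    ratios = observed / expectation
    cut = math.exp(log_threshold) - 1.0
    iprp = {tuple(idx) for idx in ratios.index if ratios[idx] > cut}
    return ratios, iprp


def select_idRP(pair_freq: pd.Series, k: int = IDRP_K) -> List[Tuple[str, str]]:
    """Top-k residue pairs by frequency, descending; ties alphabetical."""
    if not 1 <= k <= len(pair_freq):
        raise ValueError("k out of range")
    order = sorted(pair_freq.index, key=lambda t: (-pair_freq[t], t))
    return [tuple(t) for t in order[:k]]


def delta_f(f: Sequence[float], f_prime: Sequence[float], variant: str = "rss") -> float:
    """Euclidean distance between two percent composition vectors.

    ``rss`` (default): root of the sum of squared component differences;
    ``rms``: divided by the number of components under the root.
    """
    a = np.asarray(f, dtype=float)
    b = np.asarray(f_prime, dtype=float)
    if a.shape != b.shape:
        raise ValueError("composition vectors must have equal length")
    ss = float(((a - b) ** 2).sum())
    if variant == "rss":
        return math.sqrt(ss)
    if variant == "rms":
        return math.sqrt(ss / a.size)
    raise ValueError("variant must be 'rss' or 'rms'")


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested on a zero-variance vector."""


def correlation(rx: Sequence[float], ry: Sequence[float]) -> float:
    """Pearson correlation between two ratio vectors."""
    a = np.asarray(rx, dtype=float)
    b = np.asarray(ry, dtype=float)
    if a.shape != b.shape:
        raise ValueError("ratio vectors must have equal length")
    if np.isclose(a.std(), 0.0) or np.isclose(b.std(), 0.0):
        raise UndefinedCorrelationError("zero variance in a ratio vector")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class CompositionProfile:
    """Full composition summary of one interaction class."""

    class_label: str
    res_freq: pd.Series
    res_ratio: pd.Series
    pair_freq: pd.Series
    pair_ratio: pd.Series
    idR: List[str]
    ipR: Set[str]
    anti_ipR: Set[str]
    idRP: List[Tuple[str, str]]
    ipRP: Set[Tuple[str, str]]

    @classmethod
    def from_support_records(
        cls,
        records: Iterable[SupportRecord],
        class_label: str,
        background: BackgroundComposition | None = None,
        weighting: str = "per_supporting_interaction",
        idr_k: int = IDR_K,
        idrp_k: int = IDRP_K,
        ipr_hi: float = IPR_HI,
        ipr_lo: float = IPR_LO,
        iprp_log: float = IPRP_LOG,
    ) -> "CompositionProfile":
        records = list(records)
        background = background or BackgroundComposition.swissprot55()
        res_freq = residue_frequencies(records, class_label, weighting)
        res_ratio = frequency_ratio(res_freq, background)
        pair_freq = pair_frequencies(records, class_label, weighting)
        pair_ratio, iprp = pair_ratio_and_ipRP(pair_freq, background, iprp_log)
        ipr, anti = select_ipR_antiipR(res_ratio, ipr_hi, ipr_lo)
        return cls(
            class_label=class_label,
            res_freq=res_freq,
            res_ratio=res_ratio,
            pair_freq=pair_freq,
            pair_ratio=pair_ratio,
            idR=select_idR(res_freq, idr_k),
            ipR=ipr,
            anti_ipR=anti,
            idRP=select_idRP(pair_freq, idrp_k),
            ipRP=iprp,
        )

    def selections_json(self) -> str:
        return json.dumps(
            {
                "class": self.class_label,
                "idR": self.idR,
                "ipR": sorted(self.ipR),
                "anti_ipR": sorted(self.anti_ipR),
                "idRP": ["-".join(p) for p in self.idRP],
                "ipRP": sorted("-".join(p) for p in self.ipRP),
            },
            indent=2,
        )


def pair_matrix(pair_values: pd.Series) -> pd.DataFrame:
    """Symmetric 20x20 matrix view of a 210-component pair profile."""
    mat = pd.DataFrame(0.0, index=list(AA3), columns=list(AA3))
    for (a, b), v in pair_values.items():
        mat.loc[a, b] = v
        mat.loc[b, a] = v
    return mat


def plot_pair_heatmap(pair_values: pd.Series, ax=None, log1p: bool = False):
    """Optional heatmap of a pair profile (requires matplotlib)."""
    import matplotlib.pyplot as plt  # local import: plotting is optional

    from .model import THREE_TO_ONE

    mat = pair_matrix(pair_values)
    data = np.log(mat.values + 1.0) if log1p else mat.values
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(data, cmap="coolwarm")
    ax.set_xticks(range(20), [THREE_TO_ONE[t] for t in AA3])
    ax.set_yticks(range(20), [THREE_TO_ONE[t] for t in AA3])
    ax.figure.colorbar(im, ax=ax)
    return ax
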