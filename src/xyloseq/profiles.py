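"""Transcription-factor profiles over differential gene sets.

A TF profile summarizes which documented regulators most plausibly drive an
observed differential-expression response: for a DE gene set, each TF in
the regulation table is scored by how many DE genes it is documented to
regulate, and the top-K TFs (default K = 20) are retained together with the
fraction of the *total* DE gene count they cover.  Profiles from different
condition pairs are compared two ways:

* intersection of their top-K TF sets ("conserved" regulators present in
  every comparison), and
* Euclidean distance between unit-normalized fraction vectors on the union
  axis of the two profiles' TFs — for nonnegative unit vectors the distance
  lies in [0, sqrt(2)], with sqrt(2) reached exactly when the profiles share
  no TF.

A reference profile is the same construction applied to the head (default
250 genes) of an externally ranked differential-expression list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, DesignError, InputError
from .io import RegulationTable

DEFAULT_K = 20
DEFAULT_N_REF_GENES = 250


@dataclass(frozen=True)
class ProfileEntry:
    tf_name: str
    n_targets_in_de: int
    fraction: float  # n_targets_in_de / total DE genes in the input set


@dataclass(frozen=True)
class TFProfile:
    """Top-K TFs ranked by number of regulated DE genes.

    Entries are sorted by target count descending with lexicographic
    tie-breaking; TFs regulating zero DE genes never appear.  ``fraction``
    is denominated by the total DE gene count, including genes no TF
    regulates, so fractions need not sum to anything in particular.
    """

    label: str
    n_de_total: int
    entries: tuple[ProfileEntry, ...]
    K: int = DEFAULT_K

    def __post_init__(self) -> None:
        if len(self.entries) > self.K:
            raise ConfigError("profile holds more entries than K")
        for e in self.entries:
            if not 0.0 < e.fraction <= 1.0:
                raise ConfigError("profile fractions must lie in (0, 1]")

    @property
    def tf_names(self) -> list[str]:
        return [e.tf_name for e in self.entries]

    def fraction_of(self, tf: str) -> float:
        for e in self.entries:
            if e.tf_name == tf:
                return e.fraction
        return 0.0


@dataclass(frozen=True)
class NormalizedProfile:
    """A profile's fraction vector on an explicit TF axis, rescaled to unit
    norm for distance comparison."""

    axis: tuple[str, ...]
    vector: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.axis) != len(self.vector):
            raise DesignError("axis and vector lengths differ")
        v = np.asarray(self.vector)
        if (v < 0).any():
            raise ConfigError("normalized profile must be nonnegative")


def build_profile(
    de_genes: Iterable[str],
    regulation: RegulationTable,
    K: int = DEFAULT_K,
    label: str = "",
) -> TFProfile:
    """Score every TF by its documented targets within ``de_genes`` and keep
    the top ``K``."""
    de = set(de_genes)
    if not de:
        raise InputError("empty differential gene set: fractions are undefined")
    counts = []
    for tf, targets in regulation.targets_by_tf().items():
        n = len(targets & de)
        if n:
            counts.append((tf, n))
    counts.sort(key=lambda x: (-x[1], x[0]))
    total = len(de)
    entries = tuple(
        ProfileEntry(tf_name=tf, n_targets_in_de=n, fraction=n / total)
        for tf, n in counts[:K]
    )
    return TFProfile(label=label, n_de_total=total, entries=entries, K=K)


def align_and_normalize(
    p1: TFProfile, p2: TFProfile, norm: str = "l2"
) -> tuple[NormalizedProfile, NormalizedProfile]:
    """Place both profiles on the sorted union of their TF names, zero-filling
    absent TFs, and rescale each fraction vector to unit norm.

    ``norm`` is ``"l2"`` (default, makes the downstream Euclidean distance
    scale-free and bounded by sqrt(2)) or ``"l1"``.
    """
    if not p1.entries or not p2.entries:
        raise InputError("cannot normalize an empty profile")
    axis = tuple(sorted(set(p1.tf_names) | set(p2.tf_names)))
    out = []
    for p in (p1, p2):
        v = np.array([p.fraction_of(tf) for tf in axis], dtype=float)
        length = np.linalg.norm(v, ord=2 if norm == "l2" else 1)
        assert length > 0, "nonempty profile yielded a zero vector"
        out.append(NormalizedProfile(axis=axis, vector=tuple(v / length)))
    return out[0], out[1]


def euclidean_distance(s: NormalizedProfile, r: NormalizedProfile) -> float:
    """Euclidean distance d = sqrt(sum_i (TF_i,s - TF_i,r)^2) between two
    normalized profiles on the same axis."""
    if s.axis != r.axis:
        raise DesignError("profiles must share an axis; use align_and_normalize")
    return float(np.linalg.norm(np.asarray(s.vector) - np.asarray(r.vector)))


def profile_distance(p1: TFProfile, p2: TFProfile, norm: str = "l2") -> float:
    """Convenience composition: align, normalize, and measure distance."""
    a, b = align_and_normalize(p1, p2, norm=norm)
    return euclidean_distance(a, b)


def conserved_tfs(profiles: Sequence[TFProfile]) -> list[str]:
    """TFs present in the top-K of *every* profile, sorted by name.

    Order of profiles is irrelevant and duplicated profiles change nothing.
    """
    if not profiles:
        raise InputError("need at least one profile")
    common = set(profiles[0].tf_names)
    for p in profiles[1:]:
        common &= set(p.tf_names)
    return sorted(common)


def build_reference_profile(
    ranked_genes: Sequence[str],
    regulation: RegulationTable,
    n_ref_genes: int = DEFAULT_N_REF_GENES,
    K: int = DEFAULT_K,
    label: str = "reference",
) -> TFProfile:
    """Profile of the head of an external DE ranking (default: top 250)."""
    if len(ranked_genes) < n_ref_genes:
        raise InputError(
            f"ranking has {len(ranked_genes)} genes, fewer than n_ref_genes={n_ref_genes}"
        )
    return build_profile(ranked_genes[:n_ref_genes], regulation, K=K, label=label)
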