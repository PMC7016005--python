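"""Chou-Fasman alpha-helix propensity profiling and missense-impact ranking.

A ProtScale-style profile assigns each window center the uniform-weight
mean of the per-residue helix propensities (P-alpha) inside the window;
profiles are reported only where the full window fits, so a single-residue
substitution changes exactly the windows covering it, each by
(P-alpha(alt) - P-alpha(ref)) / window. Mutations are ranked most- to
least-helix-disrupting by that per-window delta magnitude.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .datasets import load_propensity_values

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}
ONE_LETTER = frozenset(THREE_TO_ONE.values())

_MUTATION_RE = re.compile(
    r"^p\.(?P<ref>[A-Z][a-z]{2}|[A-Z])(?P<pos>\d+)(?P<alt>[A-Z][a-z]{2}|[A-Z])$"
)


@dataclass(frozen=True)
class PropensityScale:
    """A named 20-residue propensity scale (all values positive)."""

    name: str
    values: Dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != ONE_LETTER:
            missing = ONE_LETTER - set(self.values)
            extra = set(self.values) - ONE_LETTER
            raise ValueError(f"scale must cover the 20 amino acids; missing={sorted(missing)} extra={sorted(extra)}")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("propensity values must be positive")

    def __getitem__(self, aa: str) -> float:
        return self.values[aa]


_SCALE_REGISTRY: Dict[str, PropensityScale] = {}


def register_scale(scale: PropensityScale) -> None:
    _SCALE_REGISTRY[scale.name] = scale


def get_scale(name: str = "chou_fasman_alpha") -> PropensityScale:
    """Look up a registered scale; the bundled Chou-Fasman P-alpha loads lazily."""
    if name not in _SCALE_REGISTRY:
        if name == "chou_fasman_alpha":
            register_scale(PropensityScale(name=name, values=load_propensity_values(name)))
        else:
            raise KeyError(f"unknown propensity scale {name!r}")
    return _SCALE_REGISTRY[name]


@dataclass(frozen=True)
class MutationSpec:
    """A protein-level single-residue substitution, e.g. p.F191S."""

    ref_aa: str
    position: int
    alt_aa: str

    def __post_init__(self) -> None:
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in ONE_LETTER:
                raise ValueError(f"unknown amino-acid code {aa!r}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"ref and alt identical in p.{self.ref_aa}{self.position}{self.alt_aa}")
        if self.position < 1:
            raise ValueError("protein positions are 1-based")

    @property
    def notation(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"


def parse_mutation(text: str) -> MutationSpec:
    """Parse one- or three-letter substitution notation into a MutationSpec."""
    m = _MUTATION_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed mutation spec {text!r}; expected p.<ref><pos><alt>")

    def norm(code: str) -> str:
        if len(code) == 3:
            if code not in THREE_TO_ONE:
                raise ValueError(f"unknown three-letter code {code!r} in {text!r}")
            return THREE_TO_ONE[code]
        if code not in ONE_LETTER:
            raise ValueError(f"unknown amino-acid code {code!r} in {text!r}")
        return code

    return MutationSpec(
        ref_aa=norm(m.group("ref")),
        position=int(m.group("pos")),
        alt_aa=norm(m.group("alt")),
    )


@dataclass
class HelixProfile:
    sequence_id: str
    offset: int
    window: int
    scores: List[Tuple[int, float]]

    def as_dict(self) -> Dict[int, float]:
        return dict(self.scores)


def window_profile(
    seq: str,
    offset: int,
    scale: PropensityScale | None = None,
    window: int = 9,
    sequence_id: str = "",
) -> HelixProfile:
    """Sliding uniform-mean propensity profile in protein coordinates.

    ``offset`` is the protein position of the first residue (1-based from
    the initiator methionine). Centers are reported only where the full
    window fits, giving L - window + 1 scores.
    """
    scale = scale or get_scale()
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    bad = set(seq) - ONE_LETTER
    if bad:
        raise ValueError(f"non-canonical residues {sorted(bad)}")
    vals = np.array([scale[aa] for aa in seq])
    means = np.convolve(vals, np.full(window, 1.0 / window), mode="valid")
    half = window // 2
    centers = [offset + half + i for i in range(len(means))]
    return HelixProfile(
        sequence_id=sequence_id,
        offset=offset,
        window=window,
        scores=list(zip(centers, means.tolist())),
    )


def apply_mutation(seq: str, offset: int, m: MutationSpec) -> str:
    """Substitute one residue in protein coordinates, checking the reference."""
    idx = m.position - offset
    if not 0 <= idx < len(seq):
        raise ValueError(
            f"position {m.position} outside sequence [{offset}, {offset + len(seq) - 1}]"
        )
    if seq[idx] != m.ref_aa:
        raise ValueError(
            f"reference mismatch at {m.position}: sequence has {seq[idx]!r}, "
            f"spec says {m.ref_aa!r}"
        )
    return seq[:idx] + m.alt_aa + seq[idx + 1:]


@dataclass
class MutationImpact:
    mutation: MutationSpec
    delta_palpha: float
    max_abs_window_delta: float
    sum_window_delta: float
    wildtype_profile: HelixProfile
    mutant_profile: HelixProfile

    @property
    def notation(self) -> str:
        return self.mutation.notation


def mutation_impact(
    seq: str,
    offset: int,
    m: MutationSpec,
    scale: PropensityScale | None = None,
    window: int = 9,
) -> MutationImpact:
    """Profile change caused by one substitution.

    With uniform weights every window covering the site shifts by exactly
    (P-alpha(alt) - P-alpha(ref)) / window and every other window is
    unchanged; both profiles are computed and subtracted rather than using
    the closed form, so the closed form stays available as a cross-check.
    """
    scale = scale or get_scale()
    mut_seq = apply_mutation(seq, offset, m)
    wt = window_profile(seq, offset, scale, window)
    mu = window_profile(mut_seq, offset, scale, window)
    deltas = np.array([ms - ws for (_, ws), (_, ms) in zip(wt.scores, mu.scores)])
    return MutationImpact(
        mutation=m,
        delta_palpha=scale[m.alt_aa] - scale[m.ref_aa],
        max_abs_window_delta=float(np.max(np.abs(deltas))) if len(deltas) else 0.0,
        sum_window_delta=float(np.sum(deltas)),
        wildtype_profile=wt,
        mutant_profile=mu,
    )


def rank_mutations(
    seq: str,
    offset: int,
    mutations: Sequence[MutationSpec],
    scale: PropensityScale | None = None,
    window: int = 9,
) -> List[MutationImpact]:
    """Order mutations most- to least-helix-disrupting.

    Sorted by decreasing |per-window delta|; ties broken by smaller protein
    position, then notation, for a deterministic total order.
    """
    impacts = [mutation_impact(seq, offset, m, scale, window) for m in mutations]
    impacts.sort(
        key=lambda im: (-im.max_abs_window_delta, im.mutation.position, im.notation)
    )
    return impacts
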