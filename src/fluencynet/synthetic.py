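"""Synthetic two-group verbal-fluency data with cluster structure.

The generator emulates the clustering/switching account of category
fluency: a subject retrieves semantically related words from one
subcategory (cluster) and occasionally switches to another.  Subjects who
know a given subcategory tend to produce several of its words together, so
words of the same subcategory acquire positively correlated response
profiles across subjects — exactly the co-occurrence structure the
correlation-network analysis presumes.

Each subject:

1. knows each lexicon word independently, with probability decreasing in
   the word's frequency rank (``p_know`` at rank 1, decaying as a power of
   rank), so common words are near-universal and rare words are known by
   few subjects;
2. draws a target retrieval length (normal, rounded, clipped to the known
   lexicon), emulating how many words fit in the timed task;
3. walks the lexicon: picks a subcategory with probability proportional to
   its number of known, not-yet-produced words, emits words within it with
   probability proportional to their Zipf-like base weights (without
   replacement), and after each emission switches subcategory with
   probability ``p_switch`` or when the subcategory is exhausted.

Group contrasts are expressed through lexicon coverage (``p_know``) and
retrieval length, the behavioural differences reported for the populations
this emulates (e.g. a hearing-impaired group producing fewer words than a
normal-hearing group).  Default profiles are calibrated so that 27-subject
groups produce on the order of 132 (nh_like) and 106 (ci_like) distinct
words.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .fluency_data import FluencyDataset

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorSpec",
    "GroupProfile",
    "generate_group",
    "generate_pair",
    "default_profiles",
    "profile_from_yaml",
    "builtin_profile",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the clustering/switching fluency generator.

    ``subcategory_sizes`` gives the number of words in each semantic
    subcategory; within a subcategory, word k (0-based) has base retrieval
    weight (k+1) ** -zipf_exponent, so early words are common and the tail
    is rare.  ``p_know`` is the per-subject probability of knowing a
    subcategory's most frequent word; knowledge decays with rank as
    p_know * (k+1) ** -knowledge_decay, so rare words are in few subjects'
    productive lexicons, as in real lexical acquisition.
    ``retrieval_mean``/``retrieval_sd`` set the per-subject word count;
    ``p_switch`` is the probability of leaving the current subcategory
    after each emission.
    """

    n_subjects: int = 27
    subcategory_sizes: tuple[int, ...] = (30, 26, 24, 20, 18, 16, 14, 14, 12, 10, 8, 8)
    zipf_exponent: float = 1.0
    knowledge_decay: float = 1.1
    retrieval_mean: float = 18.0
    retrieval_sd: float = 4.0
    p_switch: float = 0.35
    p_know: float = 0.95

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least 1 subject")
        if not self.subcategory_sizes or any(s < 1 for s in self.subcategory_sizes):
            raise ValueError("every subcategory needs at least 1 word")
        for name in ("p_switch", "p_know"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.knowledge_decay < 0:
            raise ValueError("knowledge_decay must be non-negative")
        if self.retrieval_sd < 0:
            raise ValueError("retrieval_sd must be non-negative")
        if self.retrieval_mean < 1:
            raise ValueError("retrieval_mean must be at least 1")
        if self.retrieval_mean > self.lexicon_size:
            raise ValueError(
                f"retrieval_mean {self.retrieval_mean} exceeds lexicon size "
                f"{self.lexicon_size}: no subject could reach it"
            )

    @property
    def lexicon_size(self) -> int:
        return sum(self.subcategory_sizes)

    def lexicon(self) -> dict[str, int]:
        """Mapping word -> subcategory index; word names encode both."""
        words: dict[str, int] = {}
        for k, size in enumerate(self.subcategory_sizes):
            for i in range(size):
                words[f"s{k:02d}w{i:02d}"] = k
        return words

    def base_weights(self) -> dict[str, float]:
        weights: dict[str, float] = {}
        for k, size in enumerate(self.subcategory_sizes):
            for i in range(size):
                weights[f"s{k:02d}w{i:02d}"] = (i + 1) ** -self.zipf_exponent
        return weights

    def knowledge_probs(self) -> dict[str, float]:
        """Per-word probability of being in a subject's productive lexicon."""
        probs: dict[str, float] = {}
        for k, size in enumerate(self.subcategory_sizes):
            for i in range(size):
                probs[f"s{k:02d}w{i:02d}"] = self.p_know * (i + 1) ** -self.knowledge_decay
        return probs


@dataclass(frozen=True)
class GroupProfile:
    """A labelled generator configuration for one group."""

    label: str
    spec: GeneratorSpec = field(default_factory=GeneratorSpec)

    def with_overrides(self, **overrides) -> "GroupProfile":
        return GroupProfile(label=self.label, spec=replace(self.spec, **overrides))


def default_profiles() -> tuple[GroupProfile, GroupProfile]:
    """Shipped two-group configuration (nh_like larger/longer, ci_like smaller).

    Calibrated so a 27-subject draw yields distinct-word counts on the order
    of 132 and 106 respectively, with a word-matched common vocabulary of
    several dozen words.
    """
    return builtin_profile("nh_like"), builtin_profile("ci_like")


def builtin_profile(name: str) -> GroupProfile:
    """Load one of the profiles shipped with the package (YAML)."""
    ref = resources.files("fluencynet") / "profiles" / f"{name}.yaml"
    if not ref.is_file():
        raise KeyError(f"no builtin profile named {name!r}")
    with resources.as_file(ref) as path:
        return profile_from_yaml(path)


def profile_from_yaml(path: str | Path) -> GroupProfile:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    spec_fields = dict(payload.get("spec", {}))
    if "subcategory_sizes" in spec_fields:
        spec_fields["subcategory_sizes"] = tuple(spec_fields["subcategory_sizes"])
    return GroupProfile(label=str(payload["label"]), spec=GeneratorSpec(**spec_fields))


def profile_to_yaml(profile: GroupProfile, path: str | Path) -> None:
    payload = {"label": profile.label, "spec": asdict(profile.spec)}
    payload["spec"]["subcategory_sizes"] = list(payload["spec"]["subcategory_sizes"])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def _simulate_subject(
    spec: GeneratorSpec,
    words: list[str],
    subcats: np.ndarray,
    weights: np.ndarray,
    know_probs: np.ndarray,
    rng: np.random.Generator,
) -> list[str]:
    known = rng.random(len(words)) < know_probs
    n_known = int(known.sum())
    if n_known == 0:
        return []
    target = int(round(rng.normal(spec.retrieval_mean, spec.retrieval_sd)))
    target = max(1, min(target, n_known))
    available = known.copy()
    emitted: list[str] = []
    current_cat = -1
    n_cats = int(subcats.max()) + 1
    while len(emitted) < target:
        counts = np.bincount(subcats[available], minlength=n_cats)
        if current_cat < 0 or counts[current_cat] == 0:
            probs = counts / counts.sum()
            current_cat = int(rng.choice(n_cats, p=probs))
        in_cat = available & (subcats == current_cat)
        idx = np.flatnonzero(in_cat)
        w = weights[idx]
        choice = int(rng.choice(idx, p=w / w.sum()))
        emitted.append(words[choice])
        available[choice] = False
        if rng.random() < spec.p_switch:
            current_cat = -1
    return emitted


def generate_group(
    profile: GroupProfile, seed: int | np.random.SeedSequence | None = None
) -> FluencyDataset:
    """Draw one group's fluency dataset from its profile.

    Ordered, duplicate-free response lists; every emitted word belongs to
    the configured lexicon.  Identical profile and seed give identical
    datasets.
    """
    spec = profile.spec
    rng = np.random.default_rng(seed)
    lex = spec.lexicon()
    words = list(lex)
    subcats = np.array([lex[w] for w in words], dtype=int)
    weight_map = spec.base_weights()
    weights = np.array([weight_map[w] for w in words], dtype=float)
    know_map = spec.knowledge_probs()
    know_probs = np.array([know_map[w] for w in words], dtype=float)
    subjects = []
    for i in range(spec.n_subjects):
        responses = _simulate_subject(spec, words, subcats, weights, know_probs, rng)
        if not responses:
            logger.warning(
                "subject %d of group %r knew no words and is dropped", i, profile.label
            )
            continue
        subjects.append((f"{profile.label}{i + 1:03d}", responses))
    return FluencyDataset(group_label=profile.label, subjects=subjects)


def generate_pair(
    nh_like: GroupProfile | None = None,
    ci_like: GroupProfile | None = None,
    seed: int | None = None,
) -> tuple[FluencyDataset, FluencyDataset]:
    """Independent draws of two groups from a shared master seed."""
    if nh_like is None or ci_like is None:
        default_a, default_b = default_profiles()
        nh_like = nh_like or default_a
        ci_like = ci_like or default_b
    child_a, child_b = np.random.SeedSequence(seed).spawn(2)
    return generate_group(nh_like, child_a), generate_group(ci_like, child_b)
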