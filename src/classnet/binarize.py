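"""Binary transformation (dichotomization) schemes for value networks.

Three families of thresholds convert teacher ratings and researcher
observation counts into binary tie matrices:

* ``rating_cutoff`` — a tie where the Likert rating is at or above a
  cutoff ``c`` (the field uses 1 "rarely play", 2 "sometimes play",
  3 "often play").
* ``ratio`` — row-normalize counts into the share of child *i*'s
  interactions that went to child *j* and threshold at the chance level
  ``1/(n_eff - 1)``, twice the chance level, or a fixed proportion
  (classically 5%). Ratio ties are directed: row normalization breaks the
  symmetry of the source counts.
* ``frequency`` — threshold the raw counts at half the median of all
  unordered pair frequencies (strictly above), at a nearest-rank
  percentile of that distribution, or at a fixed count (at or above).

Comparison conventions: ratio and rating schemes are inclusive (a value
exactly at the threshold is a tie); the half-median frequency rule is
strict. The frequency distribution includes zero-count pairs, each
unordered pair counted once.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .network_model import (
    BinaryNetwork,
    NetworkDomainError,
    Roster,
    ValueNetwork,
    upper_pair_values,
)

logger = logging.getLogger(__name__)

RATIO_SCHEMES = ("chance", "twice_chance", "fixed")
FREQUENCY_RULES = ("half_median", "percentile", "fixed")


@dataclass(frozen=True)
class BinarizationSpec:
    """One binarization scheme: a family plus its single parameter.

    Exactly one family applies:

    * ``family="rating_cutoff"`` with integer ``cutoff`` in 0-4;
    * ``family="ratio"`` with ``scheme`` in {chance, twice_chance, fixed},
      ``fixed_p`` required for the fixed scheme;
    * ``family="frequency"`` with ``rule`` in {half_median, percentile,
      fixed}, ``q`` for percentile and ``k`` for fixed.
    """

    family: str
    cutoff: int | None = None
    scheme: str | None = None
    fixed_p: float | None = None
    rule: str | None = None
    q: float | None = None
    k: float | None = None

    def __post_init__(self) -> None:
        if self.family == "rating_cutoff":
            if self.cutoff is None or not 0 <= int(self.cutoff) <= 4:
                raise NetworkDomainError("rating cutoff must be an integer in 0-4")
        elif self.family == "ratio":
            if self.scheme not in RATIO_SCHEMES:
                raise NetworkDomainError(f"ratio scheme must be one of {RATIO_SCHEMES}")
            if self.scheme == "fixed" and not (
                self.fixed_p is not None and 0 < self.fixed_p < 1
            ):
                raise NetworkDomainError("fixed ratio threshold needs 0 < fixed_p < 1")
        elif self.family == "frequency":
            if self.rule not in FREQUENCY_RULES:
                raise NetworkDomainError(f"frequency rule must be one of {FREQUENCY_RULES}")
            if self.rule == "percentile" and not (
                self.q is not None and 0 < self.q < 100
            ):
                raise NetworkDomainError("percentile rule needs 0 < q < 100")
            if self.rule == "fixed" and self.k is None:
                raise NetworkDomainError("fixed frequency rule needs k")
        else:
            raise NetworkDomainError(f"unknown binarization family {self.family!r}")

    @property
    def label(self) -> str:
        if self.family == "rating_cutoff":
            return f"rating>={int(self.cutoff)}"
        if self.family == "ratio":
            if self.scheme == "fixed":
                return f"ratio>={self.fixed_p:g}"
            return f"ratio:{self.scheme}"
        if self.rule == "percentile":
            return f"freq:p{self.q:g}"
        if self.rule == "fixed":
            return f"freq>={self.k:g}"
        return "freq:half_median"

    def to_dict(self) -> dict:
        out: dict = {"family": self.family}
        for key in ("cutoff", "scheme", "fixed_p", "rule", "q", "k"):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "BinarizationSpec":
        return cls(**data)


@dataclass
class RatioNetwork:
    """Row-normalized interaction shares r[i,j] = f[i,j] / sum_k f[i,k].

    Rows of children with zero total interactions stay all-zero and are
    listed in ``undefined_rows``. Ratios are asymmetric in general even
    when the source counts are symmetric.
    """

    roster: Roster
    ratios: np.ndarray
    undefined_rows: frozenset[str]

    @property
    def n(self) -> int:
        return self.roster.n


def chance_threshold(n_eff: int) -> float:
    """Chance-level interaction share ``1/(n_eff - 1)``.

    The share each classmate would receive if a child spread interactions
    uniformly over the ``n_eff - 1`` other consented children.
    """
    if n_eff < 2:
        raise NetworkDomainError("effective classroom size must be >= 2")
    return 1.0 / (n_eff - 1)


def binarize_rating(net: ValueNetwork, cutoff: int) -> BinaryNetwork:
    """Tie where the rating is at or above ``cutoff`` (inclusive)."""
    if net.kind != "rating":
        raise NetworkDomainError("binarize_rating requires a rating network")
    if not 0 <= int(cutoff) <= 4:
        raise NetworkDomainError(f"cutoff {cutoff} outside the 0-4 rating scale")
    ties = (net.values >= cutoff).astype(int)
    np.fill_diagonal(ties, 0)
    return BinaryNetwork(
        roster=net.roster,
        ties=ties,
        scheme=BinarizationSpec(family="rating_cutoff", cutoff=int(cutoff)),
        directed=net.directed,
    )


def ratio_matrix(net: ValueNetwork) -> RatioNetwork:
    """Row-normalize a count network into interaction shares."""
    if net.kind != "count":
        raise NetworkDomainError("ratio_matrix requires a count network")
    counts = net.values.astype(float)
    np.fill_diagonal(counts, 0.0)
    row_totals = counts.sum(axis=1)
    defined = row_totals > 0
    ratios = np.zeros_like(counts)
    ratios[defined] = counts[defined] / row_totals[defined, None]
    undefined = frozenset(
        cid for cid, ok in zip(net.roster.child_ids, defined) if not ok
    )
    if undefined:
        logger.info(
            "ratio_matrix: %d children with zero observed interactions: %s",
            len(undefined),
            sorted(undefined),
        )
    return RatioNetwork(roster=net.roster, ratios=ratios, undefined_rows=undefined)


def binarize_ratio(
    net: ValueNetwork,
    scheme: str = "chance",
    fixed_p: float | None = None,
    n_eff: int | None = None,
) -> BinaryNetwork:
    """Directed tie i->j where the interaction share is at or above the threshold.

    ``threshold`` is the chance level, twice the chance level, or the
    fixed proportion ``fixed_p``. ``n_eff`` defaults to the roster's
    effective size. Children with no observed interactions produce no
    outgoing ties.
    """
    spec = BinarizationSpec(family="ratio", scheme=scheme, fixed_p=fixed_p)
    if n_eff is None:
        n_eff = net.roster.effective_size
    if scheme == "chance":
        threshold = chance_threshold(n_eff)
    elif scheme == "twice_chance":
        threshold = 2.0 * chance_threshold(n_eff)
    else:
        threshold = float(fixed_p)  # validated by BinarizationSpec above
    ratios = ratio_matrix(net)
    ties = (ratios.ratios >= threshold).astype(int)
    np.fill_diagonal(ties, 0)
    logger.info("binarize_ratio: scheme=%s threshold=%.4f", scheme, threshold)
    return BinaryNetwork(roster=net.roster, ties=ties, scheme=spec, directed=True)


def frequency_cutoff(
    net: ValueNetwork,
    rule: str = "half_median",
    q: float | None = None,
    k: float | None = None,
) -> float:
    """Cutoff value for a frequency threshold rule.

    The reference distribution is the unordered off-diagonal pair
    frequencies, zeros included, each pair counted once. ``half_median``
    returns half the median; ``percentile`` the nearest-rank q-th
    percentile (the ceil(q*m/100)-th order statistic, so integer counts
    give integer cutoffs); ``fixed`` returns ``k`` verbatim.
    """
    BinarizationSpec(family="frequency", rule=rule, q=q, k=k)  # validation
    if net.kind != "count":
        raise NetworkDomainError("frequency_cutoff requires a count network")
    if rule == "fixed":
        return float(k)
    pairs = upper_pair_values(net.values)
    if rule == "half_median":
        return 0.5 * float(np.median(pairs))
    order = np.sort(pairs)
    rank = math.ceil(q * len(order) / 100.0)
    return float(order[max(rank, 1) - 1])


def binarize_frequency(
    net: ValueNetwork,
    rule: str = "half_median",
    q: float | None = None,
    k: float | None = None,
) -> BinaryNetwork:
    """Threshold raw counts into a symmetric binary network.

    The half-median rule codes a tie where the pair frequency is strictly
    above the cutoff; percentile and fixed rules are inclusive (at or
    above).
    """
    spec = BinarizationSpec(family="frequency", rule=rule, q=q, k=k)
    cutoff = frequency_cutoff(net, rule=rule, q=q, k=k)
    if rule == "half_median":
        ties = (net.values > cutoff).astype(int)
    else:
        ties = (net.values >= cutoff).astype(int)
    np.fill_diagonal(ties, 0)
    logger.info("binarize_frequency: rule=%s cutoff=%.4f", spec.label, cutoff)
    return BinaryNetwork(roster=net.roster, ties=ties, scheme=spec, directed=net.directed)


def apply_spec(net: ValueNetwork, spec: BinarizationSpec) -> BinaryNetwork:
    """Dispatch a :class:`BinarizationSpec` onto the matching scheme."""
    if spec.family == "rating_cutoff":
        return binarize_rating(net, cutoff=spec.cutoff)
    if spec.family == "ratio":
        return binarize_ratio(net, scheme=spec.scheme, fixed_p=spec.fixed_p)
    return binarize_frequency(net, rule=spec.rule, q=spec.q, k=spec.k)


#: The researcher-network schemes examined in the congruency analysis:
#: three ratio thresholds (chance, twice chance, fixed 5%) and three
#: frequency thresholds (half-median, 75th and 90th percentile).
DEFAULT_RESEARCHER_SCHEMES: tuple[BinarizationSpec, ...] = (
    BinarizationSpec(family="ratio", scheme="chance"),
    BinarizationSpec(family="ratio", scheme="twice_chance"),
    BinarizationSpec(family="ratio", scheme="fixed", fixed_p=0.05),
    BinarizationSpec(family="frequency", rule="half_median"),
    BinarizationSpec(family="frequency", rule="percentile", q=75),
    BinarizationSpec(family="frequency", rule="percentile", q=90),
)

#: Teacher-rating cutoffs examined in the congruency analysis.
DEFAULT_TEACHER_CUTOFFS: tuple[int, ...] = (1, 2, 3)
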