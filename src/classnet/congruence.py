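"""Network congruency: QAP graph correlation and Jaccard tie overlap.

The quadratic assignment procedure (QAP) tests the Pearson correlation
between two networks on a shared roster while respecting the dyadic
dependence structure: node labels of one matrix are permuted (the same
permutation applied to rows and columns), the graph correlation is
recomputed under each permutation, and the observed correlation is ranked
against that null distribution. This is the classic full-matrix
Mantel/Krackhardt form; it applies to valued and binary networks alike.

The Jaccard index ``J = C / (A + B + C)`` measures the overlap of two
binary tie sets, where ``C`` counts dyads tied in both networks and ``A``
and ``B`` count dyads tied in exactly one. Dyads absent in both are
excluded from the ratio (but reported): J is the present-tie overlap, not
the simple matching coefficient.

All statistics run over the ordered off-diagonal dyads; symmetric
networks contribute both mirrored cells, so a directed nomination network
can be compared with an undirected rating or count network on the same
``n*(n-1)``-dyad universe.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binarize import (
    DEFAULT_RESEARCHER_SCHEMES,
    DEFAULT_TEACHER_CUTOFFS,
    BinarizationSpec,
    apply_spec,
    binarize_rating,
)
from .network_model import (
    BinaryNetwork,
    Network,
    NetworkDomainError,
    RosterError,
    ValueNetwork,
    density,
    offdiag_mask,
    offdiag_values,
)

MAX_EXACT_N = 8

#: Ties at the observed statistic count toward rejection; the comparison
#: allows floating-point slack so an exactly tied permutation is never
#: dropped by rounding noise in the correlation arithmetic.
TIE_TOLERANCE = 1e-9


class DegenerateNetworkError(NetworkDomainError):
    """A network with no off-diagonal variation has undefined correlation."""


@dataclass(frozen=True)
class NullSummary:
    """Moments and central 95% quantiles of the permutation null of r."""

    mean: float
    sd: float
    q025: float
    q975: float


@dataclass(frozen=True)
class QAPResult:
    """Observed graph correlation with its permutation-null inference."""

    r_observed: float
    n_permutations: int
    p_greater: float
    p_two_sided: float
    null_summary: NullSummary
    seed: int | None = None
    exact: bool = False

    def to_dict(self) -> dict:
        return {
            "r": self.r_observed,
            "n_permutations": self.n_permutations,
            "p_greater": self.p_greater,
            "p_two_sided": self.p_two_sided,
            "null_mean": self.null_summary.mean,
            "null_sd": self.null_summary.sd,
            "null_q025": self.null_summary.q025,
            "null_q975": self.null_summary.q975,
            "seed": self.seed,
            "exact": self.exact,
        }


@dataclass(frozen=True)
class JaccardResult:
    """Tie-overlap decomposition over the ordered off-diagonal dyads."""

    only_in_a: int
    only_in_b: int
    in_both: int
    absent_in_both: int

    @property
    def jaccard(self) -> float:
        denom = self.only_in_a + self.only_in_b + self.in_both
        return self.in_both / denom if denom else 0.0

    @property
    def n_dyads(self) -> int:
        return self.only_in_a + self.only_in_b + self.in_both + self.absent_in_both

    def to_dict(self) -> dict:
        return {
            "jaccard": self.jaccard,
            "in_both": self.in_both,
            "only_in_a": self.only_in_a,
            "only_in_b": self.only_in_b,
            "absent_in_both": self.absent_in_both,
        }


def _check_same_roster(a: Network, b: Network) -> None:
    if a.roster.child_ids != b.roster.child_ids:
        raise RosterError("networks must share one roster in identical order")


def _offdiag_vector(net: Network, check: bool = True) -> np.ndarray:
    vec = offdiag_values(net.matrix).astype(float)
    if check and np.ptp(vec) == 0:
        raise DegenerateNetworkError(
            "network has no off-diagonal variation; correlation undefined"
        )
    return vec


def _corr_with_rows(a: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Pearson correlation of vector ``a`` with each row of ``rows``."""
    a0 = a - a.mean()
    r0 = rows - rows.mean(axis=1, keepdims=True)
    denom = np.sqrt((a0 @ a0) * np.einsum("ij,ij->i", r0, r0))
    return (r0 @ a0) / denom


def graph_correlation(a: Network, b: Network) -> float:
    """Pearson correlation over the ordered off-diagonal cell pairs."""
    _check_same_roster(a, b)
    va = _offdiag_vector(a)
    vb = _offdiag_vector(b)
    return float(_corr_with_rows(va, vb[None, :])[0])


def _null_from_permutations(
    a_vec: np.ndarray, b_matrix: np.ndarray, perms: np.ndarray
) -> np.ndarray:
    """Graph correlations of ``a`` with ``b`` relabeled by each permutation."""
    n = b_matrix.shape[0]
    rows, cols = np.nonzero(offdiag_mask(n))
    permuted = b_matrix[perms[:, rows], perms[:, cols]]
    return _corr_with_rows(a_vec, permuted)


def _summarize(null: np.ndarray) -> NullSummary:
    return NullSummary(
        mean=float(null.mean()),
        sd=float(null.std(ddof=1)) if null.size > 1 else 0.0,
        q025=float(np.quantile(null, 0.025)),
        q975=float(np.quantile(null, 0.975)),
    )


def qap_test(
    a: Network,
    b: Network,
    n_permutations: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
) -> QAPResult:
    """Monte-Carlo QAP test of the graph correlation between two networks.

    Draws ``n_permutations`` uniform node permutations, applies each
    simultaneously to the rows and columns of ``b`` and recomputes the
    graph correlation. P-values use the add-one convention
    ``(1 + #{r_pi >= r_obs}) / (1 + M)`` so the smallest achievable p is
    ``1/(M+1)``; ties at the observed statistic count toward rejection.
    """
    if n_permutations < 1:
        raise NetworkDomainError("n_permutations must be >= 1")
    _check_same_roster(a, b)
    a_vec = _offdiag_vector(a)
    _offdiag_vector(b)  # degeneracy check (variance is permutation-invariant)
    r_obs = graph_correlation(a, b)
    rng = np.random.default_rng(seed)
    n = a.n
    perms = rng.permuted(
        np.broadcast_to(np.arange(n), (n_permutations, n)), axis=1
    )
    null = _null_from_permutations(a_vec, b.matrix.astype(float), perms)
    p_greater = (1 + int((null >= r_obs - TIE_TOLERANCE).sum())) / (1 + n_permutations)
    p_two = (
        1 + int((np.abs(null) >= abs(r_obs) - TIE_TOLERANCE).sum())
    ) / (1 + n_permutations)
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    return QAPResult(
        r_observed=r_obs,
        n_permutations=n_permutations,
        p_greater=p_greater,
        p_two_sided=p_two,
        null_summary=_summarize(null),
        seed=seed_out,
    )


def qap_exact(a: Network, b: Network) -> QAPResult:
    """Exhaustive QAP over all ``n!`` node permutations (n <= 8).

    Deterministic reference for the Monte-Carlo test:
    ``p_greater = #{r_pi >= r_obs} / n!`` with the identity included.
    """
    _check_same_roster(a, b)
    n = a.n
    if n > MAX_EXACT_N:
        raise NetworkDomainError(
            f"exact QAP enumerates n! permutations; n={n} exceeds {MAX_EXACT_N}"
        )
    a_vec = _offdiag_vector(a)
    _offdiag_vector(b)
    r_obs = graph_correlation(a, b)
    perms = np.array(list(itertools.permutations(range(n))), dtype=int)
    null = _null_from_permutations(a_vec, b.matrix.astype(float), perms)
    n_perm = len(perms)
    return QAPResult(
        r_observed=r_obs,
        n_permutations=n_perm,
        p_greater=float((null >= r_obs - TIE_TOLERANCE).sum() / n_perm),
        p_two_sided=float(
            (np.abs(null) >= abs(r_obs) - TIE_TOLERANCE).sum() / n_perm
        ),
        null_summary=_summarize(null),
        exact=True,
    )


def jaccard(a: BinaryNetwork, b: BinaryNetwork) -> JaccardResult:
    """Jaccard overlap of two binary networks on the same roster."""
    _check_same_roster(a, b)
    va = offdiag_values(a.ties)
    vb = offdiag_values(b.ties)
    return JaccardResult(
        only_in_a=int(((va == 1) & (vb == 0)).sum()),
        only_in_b=int(((va == 0) & (vb == 1)).sum()),
        in_both=int(((va == 1) & (vb == 1)).sum()),
        absent_in_both=int(((va == 0) & (vb == 0)).sum()),
    )


# ---------------------------------------------------------------------------
# The full congruency grid: informants x binarization schemes
# ---------------------------------------------------------------------------

CHILD_LABEL = "child"
INFORMANT_PAIRS = (
    ("child", "teacher"),
    ("child", "researcher"),
    ("teacher", "researcher"),
)


@dataclass
class CongruencyReport:
    """Pairwise congruency among informants, original and binarized.

    ``qap_original`` holds the three pairwise QAP tests on the
    untransformed networks. The binary tables are keyed by
    ``(row_label, col_label)`` where rows are researcher schemes plus the
    native child network and columns are teacher cutoffs plus the child
    network, mirroring the layout of a threshold-grid report.
    """

    qap_original: dict[tuple[str, str], QAPResult]
    qap_binary: dict[tuple[str, str], QAPResult]
    jaccard_binary: dict[tuple[str, str], JaccardResult]
    densities: dict[str, float]
    n_permutations: int
    seed: int | None
    teacher_labels: list[str] = field(default_factory=list)
    researcher_labels: list[str] = field(default_factory=list)

    def qap_table(self) -> pd.DataFrame:
        """QAP r grid: rows = researcher schemes + child, cols = teacher cutoffs + child."""
        return self._grid(lambda res: res.r_observed, self.qap_binary)

    def qap_p_table(self) -> pd.DataFrame:
        return self._grid(lambda res: res.p_greater, self.qap_binary)

    def jaccard_table(self) -> pd.DataFrame:
        """Jaccard grid with the same layout as :meth:`qap_table`."""
        return self._grid(lambda res: res.jaccard, self.jaccard_binary)

    def _grid(self, extract, table) -> pd.DataFrame:
        rows = self.researcher_labels + [CHILD_LABEL]
        cols = self.teacher_labels + [CHILD_LABEL]
        frame = pd.DataFrame(index=rows, columns=cols, dtype=float)
        for (row, col), res in table.items():
            frame.loc[row, col] = extract(res)
        return frame

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "qap_original": {
                " vs ".join(k): v.to_dict() for k, v in sorted(self.qap_original.items())
            },
            "qap_binary": {
                " vs ".join(k): v.to_dict() for k, v in sorted(self.qap_binary.items())
            },
            "jaccard_binary": {
                " vs ".join(k): v.to_dict() for k, v in sorted(self.jaccard_binary.items())
            },
            "densities": dict(sorted(self.densities.items())),
        }

    def write(self, out_dir: str | Path) -> None:
        """Write the JSON report plus the QAP and Jaccard CSV grids."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "congruency_report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        self.qap_table().to_csv(out / "qap_binary.csv")
        self.jaccard_table().to_csv(out / "jaccard_binary.csv")
        pd.Series(self.densities, name="density").rename_axis("network").to_csv(
            out / "densities.csv"
        )


def congruency_grid(
    child: BinaryNetwork,
    teacher: ValueNetwork,
    observed: ValueNetwork,
    teacher_cutoffs: Sequence[int] = DEFAULT_TEACHER_CUTOFFS,
    researcher_schemes: Sequence[BinarizationSpec] = DEFAULT_RESEARCHER_SCHEMES,
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> CongruencyReport:
    """Run the full congruency analysis across informants and schemes.

    Computes (a) pairwise QAP among the three untransformed networks,
    (b) for every teacher cutoff x researcher scheme, QAP and Jaccard
    among the child network, the binarized teacher network and the
    binarized researcher network, and (c) the density of every derived
    network. Deterministic given ``seed``.
    """
    if not teacher_cutoffs or not researcher_schemes:
        raise NetworkDomainError("cutoff and scheme lists must be nonempty")
    _check_same_roster(child, teacher)
    _check_same_roster(child, observed)

    child_value = ValueNetwork(
        roster=child.roster, values=child.ties, kind="nomination", directed=True
    )
    teacher_nets = {
        f"rating>={c}": binarize_rating(teacher, c) for c in teacher_cutoffs
    }
    researcher_nets = {s.label: apply_spec(observed, s) for s in researcher_schemes}

    # One independent integer sub-seed per QAP call, in a fixed order.
    n_qap = 3 + len(teacher_nets) + len(researcher_nets) + len(teacher_nets) * len(
        researcher_nets
    )
    sub_seeds = iter(
        np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_qap).tolist()
    )

    qap_original = {
        ("child", "teacher"): qap_test(child_value, teacher, n_permutations, next(sub_seeds)),
        ("child", "researcher"): qap_test(child_value, observed, n_permutations, next(sub_seeds)),
        ("teacher", "researcher"): qap_test(teacher, observed, n_permutations, next(sub_seeds)),
    }

    qap_binary: dict[tuple[str, str], QAPResult] = {}
    jaccard_binary: dict[tuple[str, str], JaccardResult] = {}
    for t_label, t_net in teacher_nets.items():
        qap_binary[(CHILD_LABEL, t_label)] = qap_test(
            child, t_net, n_permutations, next(sub_seeds)
        )
        jaccard_binary[(CHILD_LABEL, t_label)] = jaccard(child, t_net)
    for r_label, r_net in researcher_nets.items():
        qap_binary[(r_label, CHILD_LABEL)] = qap_test(
            child, r_net, n_permutations, next(sub_seeds)
        )
        jaccard_binary[(r_label, CHILD_LABEL)] = jaccard(child, r_net)
    for t_label, t_net in teacher_nets.items():
        for r_label, r_net in researcher_nets.items():
            qap_binary[(r_label, t_label)] = qap_test(
                t_net, r_net, n_permutations, next(sub_seeds)
            )
            jaccard_binary[(r_label, t_label)] = jaccard(t_net, r_net)

    densities = {CHILD_LABEL: density(child)}
    for label, net in {**teacher_nets, **researcher_nets}.items():
        densities[label] = density(net)

    return CongruencyReport(
        qap_original=qap_original,
        qap_binary=qap_binary,
        jaccard_binary=jaccard_binary,
        densities=densities,
        n_permutations=n_permutations,
        seed=seed,
        teacher_labels=list(teacher_nets),
        researcher_labels=list(researcher_nets),
    )
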