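"""Deterministic generators of planted-cluster MSAs and two-state structures.

These generators make every pipeline stage testable without sequence
databases or GPU inference. The MSA generator emulates the block structure
density-based clustering exploits — families sharing signature residues at
family-specific columns over a mutated common background — and the structure
generator emulates a two-state reference pair in which a contiguous segment
(think of the intracellular swing of TM6 on receptor activation) is
displaced between the active and inactive templates.

Closed forms
------------
With signature-column sets disjoint across families, background mutation
rate ``mu``, and gap rate ``gamma``, the expected one-hot squared Euclidean
distance between two rows is ``2 x E[Hamming]`` over match columns, with

* within a family: ``E[H] = (L - s) * p_diff`` where ``p_diff`` is the
  per-column disagreement probability of two independently mutated/gapped
  copies of the same background column;
* between families: the ``2s`` signature columns disagree (up to a
  ``mu / 19`` coincidence), plus ``(L - 2s) * p_diff`` background columns.

At ``mu = gamma = 0`` this reduces to within-distance 0 and between squared
distance ``4s`` (two families with ``s`` signature columns each).

For structures, superposing on the undisplaced core and measuring over all
residues gives RMSD ``d * sqrt(f)`` exactly, where ``d`` is the segment
displacement and ``f`` the displaced fraction. The full Kabsch fit over the
whole selection yields a smaller gap, so the generator calibrates ``d``
numerically (Brent root finding) when a target Kabsch gap is requested.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ArgumentError
from .msa import Msa
from .structure import (
    AtomRecord,
    Chain,
    Residue,
    ResidueSelection,
    StructureModel,
    kabsch_rmsd,
    superposed_rmsd,
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# planted-family MSAs


@dataclass(frozen=True)
class TwoStateMsaSpec:
    """Parameters of the planted-family MSA generator.

    Each family owns ``family_signature_columns`` columns (disjoint across
    families) where all its rows carry a family-specific residue; every
    other column starts from a shared background consensus and is mutated
    and gapped independently per row.
    """

    n_families: int = 2
    rows_per_family: int = 20
    match_length: int = 80
    family_signature_columns: int = 6
    background_mutation_rate: float = 0.02
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.rows_per_family < 1:
            raise ArgumentError("need at least one family with one row")
        if self.n_families * self.family_signature_columns > self.match_length:
            raise ArgumentError(
                "signature columns exceed match length: "
                f"{self.n_families} x {self.family_signature_columns} > "
                f"{self.match_length}"
            )
        for rate in (self.background_mutation_rate, self.gap_rate):
            if not 0.0 <= rate <= 1.0:
                raise ArgumentError(f"rates must be in [0, 1], got {rate}")

    # -- closed forms ------------------------------------------------------

    def _p_diff_background(self) -> float:
        mu, gamma = self.background_mutation_rate, self.gap_rate
        # residue disagreement of two mutated copies of the same column
        p_res = 2 * mu * (1 - mu) + mu * mu * (18.0 / 19.0)
        # gap symbol disagreement folded in: same iff both gapped, or both
        # retained and residues agree
        p_same = gamma * gamma + (1 - gamma) ** 2 * (1 - p_res)
        return 1.0 - p_same

    def expected_squared_distances(self) -> tuple[float, float]:
        """Expected one-hot squared distances (within-family, between-family)."""
        L, s = self.match_length, self.family_signature_columns
        mu, gamma = self.background_mutation_rate, self.gap_rate
        p_diff = self._p_diff_background()
        within = (L - s) * p_diff
        sig_diff = 1.0 - (1 - gamma) * mu / 19.0
        between = 2 * s * sig_diff + (L - 2 * s) * p_diff
        return 2.0 * within, 2.0 * between

    def suggested_epsilon(self) -> float:
        """Epsilon between the within- and between-family distance regimes."""
        w2, b2 = self.expected_squared_distances()
        return float(np.sqrt((w2 + b2) / 2.0))


def make_two_state_msa(spec: TwoStateMsaSpec) -> tuple[Msa, list[int]]:
    """Generate a planted-family alignment and its family labels.

    Returns ``(msa, labels)`` with one label per non-query row; row ids are
    ``fam{f:02d}_r{i:03d}`` so the family tag survives clustering and can
    key a mock-predictor rule table. Bit-reproducible per seed.
    """
    rng = np.random.default_rng(spec.seed)
    L, s = spec.match_length, spec.family_signature_columns
    background = rng.integers(0, 20, size=L)
    query = "".join(_AA20[i] for i in background)

    sig_cols = {
        f: list(range(f * s, (f + 1) * s)) for f in range(spec.n_families)
    }
    rows: list[tuple[str, str]] = [("query", query)]
    labels: list[int] = []
    for f in range(spec.n_families):
        own = np.zeros(L, dtype=bool)
        own[sig_cols[f]] = True
        for i in range(spec.rows_per_family):
            codes = background.copy()
            # offset in 1..19 so the signature never equals the background
            codes[own] = (background[own] + 1 + (f % 19)) % 20
            mutate = (rng.random(L) < spec.background_mutation_rate) & ~own
            codes[mutate] = (
                codes[mutate] + rng.integers(1, 20, size=int(mutate.sum()))
            ) % 20
            chars = np.array(list(_AA20))[codes]
            gap = (rng.random(L) < spec.gap_rate) & ~own
            chars[gap] = "-"
            rows.append((f"fam{f:02d}_r{i:03d}", "".join(chars)))
            labels.append(f)
    return Msa(tuple(rows)), labels


# ---------------------------------------------------------------------------
# two-state toy structures


@dataclass(frozen=True)
class TwoStateStructureSpec:
    """Parameters of the two-state CA-trace generator.

    The scaffold is an ideal-helix-like CA trace. The last
    ``displaced_fraction`` of residues is rigidly translated between the
    inactive and active templates. ``displacement`` (Angstrom) may be given
    directly; when ``None`` it is calibrated so the Kabsch RMSD between the
    references over all CA atoms equals ``target_gap``.
    """

    n_residues: int = 80
    displacement: float | None = None
    target_gap: float = 5.0
    displaced_fraction: float = 0.3
    noise_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 10:
            raise ArgumentError("need at least 10 residues")
        if self.displacement is not None and self.displacement <= 0:
            raise ArgumentError("displacement must be positive")
        if not 0.0 < self.displaced_fraction < 1.0:
            raise ArgumentError("displaced_fraction must be in (0, 1)")
        if self.noise_sigma < 0:
            raise ArgumentError("noise_sigma must be >= 0")


def _helix_trace(n: int) -> np.ndarray:
    """Ideal alpha-helix-like CA trace: 2.3 A radius, 1.5 A rise, 100 deg turn."""
    t = np.arange(n) * np.deg2rad(100.0)
    return np.stack(
        [2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)], axis=1
    )


def _ca_model(coords: np.ndarray, model_id: str, plddt: float | np.ndarray) -> StructureModel:
    plddt_arr = np.broadcast_to(np.asarray(plddt, dtype=np.float64), (len(coords),))
    residues = tuple(
        Residue(
            i + 1,
            "ALA",
            (AtomRecord("CA", "C", (float(x), float(y), float(z))),),
            float(plddt_arr[i]),
        )
        for i, (x, y, z) in enumerate(coords)
    )
    return StructureModel((Chain("A", residues),), model_id=model_id)


@dataclass(frozen=True)
class ReferencePair:
    """Active/inactive reference pair plus a decoy and a noisy-state sampler."""

    ref_active: StructureModel
    ref_inactive: StructureModel
    decoy: StructureModel
    selection: ResidueSelection
    displacement: float
    segment_start: int  # 0-based index of the first displaced residue
    spec: TwoStateStructureSpec
    _coords: Mapping[str, np.ndarray]

    @property
    def displaced_fraction(self) -> float:
        return self.spec.displaced_fraction

    def template_coords(self, state: str) -> np.ndarray:
        try:
            return self._coords[state]
        except KeyError:
            raise ArgumentError(f"unknown state {state!r}") from None

    def sampler(
        self,
        state: Literal["active", "inactive", "decoy"],
        seed: int,
        plddt: float | np.ndarray = 90.0,
        noise_sigma: float | None = None,
    ) -> StructureModel:
        """A noisy copy of the chosen template with the given plDDT."""
        sigma = self.spec.noise_sigma if noise_sigma is None else noise_sigma
        rng = np.random.default_rng(seed)
        coords = self.template_coords(state) + rng.normal(
            0.0, sigma, size=(self.spec.n_residues, 3)
        )
        return _ca_model(coords, f"{state}_sample", plddt)

    def gap(self, fit_on: Literal["selection", "core"] = "selection") -> float:
        """RMSD between the references over all CA atoms.

        ``fit_on="core"`` superposes on the undisplaced scaffold (closed
        form ``displacement * sqrt(displaced_fraction)``); the default fits
        the whole selection with Kabsch.
        """
        a = self._coords["active"]
        i = self._coords["inactive"]
        if fit_on == "core":
            core = slice(0, self.segment_start)
            return superposed_rmsd(a, i, a[core], i[core])
        return kabsch_rmsd(a, i)[0]


def make_two_state_structures(spec: TwoStateStructureSpec) -> ReferencePair:
    """Build the active/inactive reference pair, a decoy, and a sampler.

    The decoy's displaced segment is moved off the active-inactive axis by
    1.5 x the displacement, so it sits several Angstrom from both
    references and exercises the exclusion branches of the classification
    rules.
    """
    n = spec.n_residues
    base = _helix_trace(n)
    seg_start = int(round(n * (1.0 - spec.displaced_fraction)))
    seg = slice(seg_start, n)

    def build(offset: np.ndarray) -> np.ndarray:
        coords = base.copy()
        coords[seg] = coords[seg] + offset
        return coords

    def kabsch_gap(d: float) -> float:
        return kabsch_rmsd(build(np.array([d, 0.0, 0.0])), base)[0]

    if spec.displacement is not None:
        d = spec.displacement
    else:
        # kabsch_gap(d) <= d * sqrt(f), so d = target / sqrt(f) brackets from
        # below; 6x is a generous upper bracket.
        lo = spec.target_gap / np.sqrt((n - seg_start) / n)
        hi = 6.0 * lo
        d = float(brentq(lambda x: kabsch_gap(x) - spec.target_gap, lo * 0.99, hi))

    active = build(np.array([d, 0.0, 0.0]))
    inactive = base
    decoy = build(np.array([0.0, 1.5 * d, 0.0]))
    coords = {"active": active, "inactive": inactive, "decoy": decoy}
    selection = ResidueSelection((("A", 1, n),), "CA")
    return ReferencePair(
        ref_active=_ca_model(active, "ref_active", 100.0),
        ref_inactive=_ca_model(inactive, "ref_inactive", 100.0),
        decoy=_ca_model(decoy, "ref_decoy", 100.0),
        selection=selection,
        displacement=float(d),
        segment_start=seg_start,
        spec=spec,
        _coords=coords,
    )


# ---------------------------------------------------------------------------
# mock-predictor rule tables for ligand scenarios


#: (active, inactive, decoy) state fractions per scenario. The agonist and
#: antagonist splits are recognizable receptor-landscape test vectors; apo
#: splits evenly between the states.
SCENARIO_FRACTIONS: dict[str, tuple[float, float, float]] = {
    "agonist": (0.75, 0.18, 0.07),
    "antagonist": (0.65, 0.29, 0.06),
    "apo": (0.5, 0.5, 0.0),
}

#: Fraction of the top-confidence pool planted as active, per scenario
#: (agonist 19/23, antagonist 9/23, apo half).
SCENARIO_TOP_ACTIVE_FRACTION: dict[str, float] = {
    "agonist": 19.0 / 23.0,
    "antagonist": 9.0 / 23.0,
    "apo": 0.5,
}

_HI_PLDDT = (88.0, 1.0)
_LO_PLDDT = (76.0, 2.0)
_DECOY_PLDDT = (55.0, 3.0)
_HI_IPTM = (0.85, 0.01)
_LO_IPTM = (0.55, 0.02)
_DECOY_IPTM = (0.30, 0.02)


@dataclass(frozen=True)
class MockRule:
    """State and confidence-score distributions for one cluster."""

    state: Literal["active", "inactive", "decoy"]
    plddt: tuple[float, float] = _LO_PLDDT  # (mean, sd)
    iptm: tuple[float, float] = _LO_IPTM


@dataclass(frozen=True)
class MockRuleTable:
    """Maps prediction jobs to mock rules by cluster label or family tag.

    Family tags are the id prefix before the first underscore (the planted
    generator writes ids like ``fam03_r007``). Resolution order: label,
    tag, default; an unresolvable job raises :class:`RuleConfigError`.
    """

    by_label: Mapping[int, MockRule] = None
    by_tag: Mapping[str, MockRule] = None
    default: MockRule | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "by_label", dict(self.by_label or {}))
        object.__setattr__(self, "by_tag", dict(self.by_tag or {}))

    def resolve(self, label: int | None, row_ids: Sequence[str]) -> MockRule:
        from .errors import RuleConfigError

        if label is not None and label in self.by_label:
            return self.by_label[label]
        for rid in row_ids[1:]:  # skip the merged query row
            tag = rid.split("_", 1)[0]
            if tag in self.by_tag:
                return self.by_tag[tag]
        if self.default is not None:
            return self.default
        raise RuleConfigError(
            f"no rule for cluster label={label!r} (ids {list(row_ids[:3])}...) "
            "and no default rule configured"
        )

    def planted_state(self, tag_or_label: str | int) -> str:
        rule = (
            self.by_label.get(tag_or_label)
            if isinstance(tag_or_label, int)
            else self.by_tag.get(tag_or_label)
        )
        if rule is None:
            raise ArgumentError(f"no rule for {tag_or_label!r}")
        return rule.state


def make_mock_rules(
    labels: Sequence[str] | Sequence[int],
    scenario: Literal["agonist", "antagonist", "apo"],
    top_pool: tuple[int, int] | None = None,
) -> MockRuleTable:
    """Plant a ligand scenario over a set of cluster labels or family tags.

    The agonist scenario maps most clusters to the active state, the
    antagonist scenario shifts weight to inactive, and apo splits evenly;
    each scenario additionally plants a high-confidence pool of
    ``ceil(0.10 * n)`` clusters (override its active/inactive composition
    via ``top_pool``) whose plDDT/ipTM distributions dominate the rest, so
    top-fraction rankings have a known composition.
    """
    labels = list(labels)
    n = len(labels)
    if n == 0:
        raise ArgumentError("labels must be nonempty")
    if scenario not in SCENARIO_FRACTIONS:
        raise ArgumentError(f"unknown scenario {scenario!r}")
    fa, fi, _fd = SCENARIO_FRACTIONS[scenario]
    n_active = round(fa * n)
    n_inactive = round(fi * n)
    n_decoy = n - n_active - n_inactive
    if n_decoy < 0:
        n_inactive += n_decoy
        n_decoy = 0

    k = int(np.ceil(0.10 * n))
    if top_pool is None:
        hi_active = round(SCENARIO_TOP_ACTIVE_FRACTION[scenario] * k)
        hi_inactive = k - hi_active
    else:
        hi_active, hi_inactive = top_pool
    hi_active = min(hi_active, n_active)
    hi_inactive = min(hi_inactive, n_inactive)

    states = (
        ["active"] * n_active + ["inactive"] * n_inactive + ["decoy"] * n_decoy
    )
    rules: dict = {}
    seen_active = seen_inactive = 0
    for lab, state in zip(labels, states):
        if state == "active":
            hi = seen_active < hi_active
            seen_active += 1
            rule = MockRule(
                "active",
                _HI_PLDDT if hi else _LO_PLDDT,
                _HI_IPTM if hi else _LO_IPTM,
            )
        elif state == "inactive":
            hi = seen_inactive < hi_inactive
            seen_inactive += 1
            rule = MockRule(
                "inactive",
                _HI_PLDDT if hi else _LO_PLDDT,
                _HI_IPTM if hi else _LO_IPTM,
            )
        else:
            rule = MockRule("decoy", _DECOY_PLDDT, _DECOY_IPTM)
        rules[lab] = rule
    if labels and isinstance(labels[0], int):
        return MockRuleTable(by_label=rules)
    return MockRuleTable(by_tag=rules)


def stable_job_key(row_ids: Sequence[str]) -> int:
    """Deterministic 31-bit key for a job, derived from its row ids."""
    return zlib.crc32("|".join(row_ids).encode()) & 0x7FFFFFFF
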