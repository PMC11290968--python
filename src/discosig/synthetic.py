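"""Synthetic data generators with planted, recoverable ground truth.

Each generator emulates one input class of the analysis:

* ``simulate_perturbation_set`` — multi-cell-line differential z-score
  profiles of a drug perturbation (level-5-style), with planted
  consistently up/down genes that fire in a responder subset of cell
  lines over standard-normal background noise;
* ``simulate_cohort`` — a labelled tumor expression cohort with planted
  subgroup markers, an optional subgroup whose markers are anti-aligned
  with a supplied drug signature (the discordant, predicted-responder
  subgroup), and exponential survival whose hazard depends on the
  patient's quartile of a planted gene set's mean expression;
* ``simulate_dependency_table`` — per-gene, per-cell-line dependency
  scores with planted essential genes (negative scores = required);
* ``simulate_dose_response`` — two-agent combination surfaces whose
  single-agent margins follow 4PL inhibition curves and whose
  combination cells carry a planted excess over the HSA expectation.

All generators are pure functions of their spec: the same spec and seed
reproduce the output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import ExpressionCohort, SurvivalRecord
from .consensus import ConsensusSignature
from .doseresponse import DoseResponseSurface
from .errors import ValidationError
from .matrix import MatrixTable
from .survival import quartile_stratify

# cohort-wide per-cell Gaussian expression noise, log2 units
COHORT_NOISE_SD = 1.0
# baseline per-gene mean expression, log2 units (microarray-style)
COHORT_BASELINE_MEAN = 7.0
COHORT_BASELINE_SD = 1.0
# baseline median overall survival of the simulated cohort, days
BASELINE_MEDIAN_SURVIVAL_DAYS = 1825.0

DEFAULT_SUBGROUP_PROPORTIONS = {"WNT": 0.10, "SHH": 0.30, "G3": 0.25, "G4": 0.35}


def _gene_ids(n: int, taken: set[str] | None = None) -> list[str]:
    out: list[str] = []
    i = 0
    taken = taken or set()
    while len(out) < n:
        g = f"GENE{i:05d}"
        if g not in taken:
            out.append(g)
        i += 1
    return out


# ---------------------------------------------------------------------------
# perturbation profiles


@dataclass
class PerturbationSimSpec:
    """Conditions for a simulated multi-cell-line perturbation screen.

    Defaults mirror an 18-cell-line screen with strong planted
    responses (mean |z| = 4) firing in half the lines over unit noise.
    """

    n_genes: int = 1000
    n_cell_lines: int = 18
    n_up: int = 50
    n_down: int = 50
    planted_effect: float = 4.0
    responder_fraction: float = 0.5
    noise_sd: float = 1.0
    timepoints: list[str] = field(default_factory=lambda: ["24 h"])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValidationError(
                f"n_up + n_down = {self.n_up + self.n_down} exceeds n_genes = {self.n_genes}"
            )
        if not 0 < self.responder_fraction <= 1:
            raise ValidationError(
                f"responder_fraction must be in (0, 1], got {self.responder_fraction}"
            )
        if self.noise_sd <= 0:
            raise ValidationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if "24 h" not in self.timepoints:
            raise ValidationError("timepoints must include '24 h'")
        if self.n_cell_lines < 2:
            raise ValidationError("need at least 2 cell lines")


def simulate_perturbation_set(
    spec: PerturbationSimSpec,
) -> tuple[MatrixTable, dict[str, str]]:
    """Simulate a genes x (cell line, timepoint) z-score matrix.

    Planted genes receive ``z ~ N(+-planted_effect, noise_sd)`` in a
    random responder subset of ``round(responder_fraction * n_cell_lines)``
    cell lines at the "24 h" timepoint and pure noise everywhere else;
    background genes are pure noise throughout.  Returns the matrix and
    the ``gene -> "up"|"down"`` truth map.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    planted = rng.choice(spec.n_genes, size=spec.n_up + spec.n_down, replace=False)
    up_idx, down_idx = planted[: spec.n_up], planted[spec.n_up :]
    truth = {genes[i]: "up" for i in up_idx}
    truth.update({genes[i]: "down" for i in down_idx})

    lines = [f"CL{i:02d}" for i in range(spec.n_cell_lines)]
    n_resp = max(1, round(spec.responder_fraction * spec.n_cell_lines))
    cols: list[str] = []
    col_meta: dict[str, dict[str, str]] = {}
    blocks: list[np.ndarray] = []
    for tp in spec.timepoints:
        z = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_cell_lines))
        if tp == "24 h":
            for sign, idx in ((+1.0, up_idx), (-1.0, down_idx)):
                for i in idx:
                    responders = rng.choice(spec.n_cell_lines, size=n_resp, replace=False)
                    z[i, responders] += sign * spec.planted_effect
        blocks.append(z)
        for line in lines:
            col = f"{line}:{tp}"
            cols.append(col)
            col_meta[col] = {"cell_line": line, "timepoint": tp}
    # columns are laid out timepoint-major to match the loop above
    values = np.concatenate(blocks, axis=1)
    table = MatrixTable(row_ids=genes, col_ids=cols, values=values, col_meta=col_meta)
    return table, truth


# ---------------------------------------------------------------------------
# patient cohorts


@dataclass
class CohortSimSpec:
    """Conditions for a simulated labelled tumor cohort.

    Defaults mirror a 76-patient four-subgroup cohort on the log2 scale
    with unit per-cell noise.  ``discordant_subgroup`` marks the
    subgroup whose planted markers are anti-aligned with a supplied
    drug signature; ``survival_hazard_ratio`` is the planted Q4-vs-Q1
    hazard ratio for the mean expression of ``survival_geneset``.
    """

    n_genes: int = 1000
    n_patients: int = 76
    subgroup_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_PROPORTIONS)
    )
    n_markers_per_subgroup: int = 20
    marker_log2fc: float = 2.0
    discordant_subgroup: str | None = None
    survival_geneset: list[str] | None = None
    survival_hazard_ratio: float = 1.0
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.subgroup_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"subgroup proportions sum to {total}, expected 1")
        if self.discordant_subgroup is not None and (
            self.discordant_subgroup not in self.subgroup_proportions
        ):
            raise ValidationError(
                f"discordant_subgroup {self.discordant_subgroup!r} not among "
                f"{sorted(self.subgroup_proportions)}"
            )
        if self.survival_hazard_ratio <= 0:
            raise ValidationError("survival_hazard_ratio must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ValidationError(f"censor_rate must be in [0, 1), got {self.censor_rate}")
        if self.survival_hazard_ratio != 1.0 and not self.survival_geneset:
            raise ValidationError(
                "a survival_geneset is required to plant a hazard ratio != 1"
            )


@dataclass
class CohortTruth:
    """Ground truth recorded by :func:`simulate_cohort`."""

    markers: dict[str, dict[str, float]]  # subgroup -> gene -> planted log2 shift
    discordant_subgroup: str | None
    survival_geneset: list[str]
    quartile: dict[str, str]  # patient -> Q1..Q4 on the geneset score
    hazard_multiplier: dict[str, float]


def _assign_subgroups(
    spec: CohortSimSpec, rng: np.random.Generator
) -> list[str]:
    """Largest-remainder apportionment of patients to subgroups, then a
    seeded shuffle so subgroup membership is not positional."""
    names = sorted(spec.subgroup_proportions)
    raw = {s: spec.subgroup_proportions[s] * spec.n_patients for s in names}
    counts = {s: int(math.floor(raw[s])) for s in names}
    short = spec.n_patients - sum(counts.values())
    for s in sorted(names, key=lambda s: raw[s] - counts[s], reverse=True)[:short]:
        counts[s] += 1
    labels = [s for s in names for _ in range(counts[s])]
    rng.shuffle(labels)
    return labels


def simulate_cohort(
    spec: CohortSimSpec,
    drug_signature: ConsensusSignature | None = None,
) -> tuple[ExpressionCohort, CohortTruth]:
    """Simulate a labelled expression cohort with planted structure.

    Marker planting: every subgroup gets ``n_markers_per_subgroup``
    private genes shifted by ``+marker_log2fc``; the discordant
    subgroup's markers are instead placed on the genes it shares with
    the drug signature, shifted *against* the signature
    (``-sign(consensus_z) * marker_log2fc``), so that subgroup's
    disease signature is discordant with the drug by construction.

    Survival: times are exponential with a baseline hazard calibrated to
    a median of ~5 years; a patient's hazard is multiplied by
    ``survival_hazard_ratio ** (q/3)`` where ``q`` is their 0-based
    quartile of mean ``survival_geneset`` expression, so the planted
    Q4-vs-Q1 hazard ratio equals ``survival_hazard_ratio``.  Censoring
    is independent: with probability ``censor_rate`` the event is
    replaced by censoring at a uniform fraction of the event time.
    """
    if spec.discordant_subgroup is not None and drug_signature is None:
        raise ValidationError("discordant_subgroup set but no drug_signature supplied")
    rng = np.random.default_rng(spec.seed)

    # gene universe: drug-signature genes and the survival gene set are
    # guaranteed members so shared-gene alignment downstream is nonempty
    reserved: list[str] = []
    if drug_signature is not None:
        reserved.extend(drug_signature.genes)
    for g in spec.survival_geneset or []:
        if g not in reserved:
            reserved.append(g)
    if len(reserved) > spec.n_genes:
        raise ValidationError(
            f"n_genes = {spec.n_genes} too small for {len(reserved)} reserved genes"
        )
    genes = reserved + _gene_ids(spec.n_genes - len(reserved), taken=set(reserved))
    patients = [f"PT{i:03d}" for i in range(spec.n_patients)]
    labels = _assign_subgroups(spec, rng)
    subgroup = dict(zip(patients, labels))

    baseline = rng.normal(COHORT_BASELINE_MEAN, COHORT_BASELINE_SD, size=spec.n_genes)
    expr = baseline[:, None] + rng.normal(
        0.0, COHORT_NOISE_SD, size=(spec.n_genes, spec.n_patients)
    )

    # marker planting
    gene_index = {g: i for i, g in enumerate(genes)}
    markers: dict[str, dict[str, float]] = {}
    sig_genes = set(drug_signature.genes) if drug_signature is not None else set()
    free_pool = [g for g in genes if g not in sig_genes and g not in (spec.survival_geneset or [])]
    pool_pos = 0
    for s in sorted(spec.subgroup_proportions):
        cols = [j for j, p in enumerate(patients) if subgroup[p] == s]
        planted: dict[str, float] = {}
        if s == spec.discordant_subgroup:
            assert drug_signature is not None
            for g in drug_signature.genes:
                shift = -math.copysign(
                    spec.marker_log2fc, drug_signature.entries[g].consensus_z
                )
                planted[g] = shift
        else:
            chosen = free_pool[pool_pos : pool_pos + spec.n_markers_per_subgroup]
            pool_pos += spec.n_markers_per_subgroup
            if len(chosen) < spec.n_markers_per_subgroup:
                raise ValidationError("n_genes too small for the requested marker counts")
            planted = {g: spec.marker_log2fc for g in chosen}
        for g, shift in planted.items():
            expr[gene_index[g], cols] += shift
        markers[s] = planted

    cohort_expr = MatrixTable(row_ids=genes, col_ids=patients, values=expr)

    # survival
    geneset = list(spec.survival_geneset or [])
    if geneset:
        rows = [gene_index[g] for g in geneset]
        score = dict(zip(patients, expr[rows].mean(axis=0).astype(float)))
        quartile = quartile_stratify(score)
        q_index = {"Q1": 0, "Q2": 1, "Q3": 2, "Q4": 3}
        multiplier = {
            p: spec.survival_hazard_ratio ** (q_index[quartile[p]] / 3.0) for p in patients
        }
    else:
        quartile = {}
        multiplier = {p: 1.0 for p in patients}

    base_rate = math.log(2.0) / BASELINE_MEDIAN_SURVIVAL_DAYS
    survival: dict[str, SurvivalRecord] = {}
    for p in patients:
        t = rng.exponential(1.0 / (base_rate * multiplier[p]))
        event = 1
        if spec.censor_rate > 0 and rng.random() < spec.censor_rate:
            event = 0
            t *= rng.random()
        survival[p] = SurvivalRecord(os_time=max(t, 1e-6), os_event=event)

    cohort = ExpressionCohort(
        expr=cohort_expr, subgroup=subgroup, survival=survival, scale="log2"
    )
    truth = CohortTruth(
        markers=markers,
        discordant_subgroup=spec.discordant_subgroup,
        survival_geneset=geneset,
        quartile=quartile,
        hazard_multiplier=multiplier,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# dependency tables


def simulate_dependency_table(
    essential_genes: list[str],
    n_genes: int = 500,
    n_cell_lines: int = 20,
    seed: int = 0,
) -> MatrixTable:
    """Simulate an RNAi-style dependency score table.

    Essential genes score ``N(-1.5, 0.3)`` per cell line and the rest
    ``N(0, 0.3)``: negative means the line requires the gene, matching
    the dependency-portal convention.  The essential genes are
    guaranteed members of the generated gene universe.
    """
    if len(essential_genes) > n_genes:
        raise ValidationError("more essential genes than n_genes")
    rng = np.random.default_rng(seed)
    genes = list(essential_genes) + _gene_ids(
        n_genes - len(essential_genes), taken=set(essential_genes)
    )
    lines = [f"DEP_CL{i:02d}" for i in range(n_cell_lines)]
    scores = rng.normal(0.0, 0.3, size=(n_genes, n_cell_lines))
    scores[: len(essential_genes)] += -1.5
    return MatrixTable(row_ids=genes, col_ids=lines, values=scores)


# ---------------------------------------------------------------------------
# dose-response surfaces


@dataclass
class SynergySimSpec:
    """Conditions for a simulated two-agent combination assay.

    Default dose grids bracket the default EC50s (10 concentration
    units, Hill slope 1) so single-agent inhibition spans 20-80%,
    keeping combination cells with planted excess in [-15, +25] inside
    the [0, 110] clip window (the clip never fires on clean surfaces).
    """

    doses_a: list[float] = field(default_factory=lambda: [0.0, 2.5, 5.0, 10.0, 20.0, 40.0])
    doses_b: list[float] = field(default_factory=lambda: [0.0, 2.5, 5.0, 10.0, 20.0, 40.0])
    ec50_a: float = 10.0
    ec50_b: float = 10.0
    hill_a: float = 1.0
    hill_b: float = 1.0
    planted_excess: float = 0.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, grid in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            arr = np.asarray(grid, dtype=float)
            if len(arr) < 2 or np.any(np.diff(arr) <= 0):
                raise ValidationError(f"{name} must be strictly ascending with >= 2 doses")
            if arr[0] != 0:
                raise ValidationError(f"{name} must start at 0")
        if self.ec50_a <= 0 or self.ec50_b <= 0:
            raise ValidationError("EC50s must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def _four_pl_inhibition(dose: np.ndarray, ec50: float, hill: float) -> np.ndarray:
    out = np.zeros_like(dose, dtype=float)
    nz = dose > 0
    out[nz] = 100.0 / (1.0 + (ec50 / dose[nz]) ** hill)
    return out


def simulate_dose_response(spec: SynergySimSpec) -> DoseResponseSurface:
    """Simulate a combination inhibition surface with planted HSA excess.

    Single-agent margins follow the exact 4PL curves; each combination
    cell equals ``max(single-agent inhibitions) + planted_excess``
    plus Gaussian noise, clipped to [0, 110].
    """
    da = np.asarray(spec.doses_a, dtype=float)
    db = np.asarray(spec.doses_b, dtype=float)
    inh_a = _four_pl_inhibition(da, spec.ec50_a, spec.hill_a)
    inh_b = _four_pl_inhibition(db, spec.ec50_b, spec.hill_b)
    response = np.zeros((len(da), len(db)))
    response[:, 0] = inh_a
    response[0, :] = inh_b
    combo = np.maximum.outer(inh_a[1:], inh_b[1:]) + spec.planted_excess
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        combo = combo + rng.normal(0.0, spec.noise_sd, size=combo.shape)
    response[1:, 1:] = np.clip(combo, 0.0, 110.0)
    return DoseResponseSurface(
        doses_a=da, doses_b=db, response=response, response_kind="inhibition"
    )
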