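"""Synthetic probe-level cohorts and PBMC-like mixtures with ground truth.

The generator emulates the statistical structure of a three-group sorted
cell-type study — healthy baseline, day-7 yellow-fever-vaccinated, and SLE
— at the probe level:

* per-gene baseline log2 abundance, shared probe affinities within a
  probe-set (fixed across arrays, cancelling in pairwise comparisons),
  per-array measurement noise drawn independently per probe, and a
  residual per-probe jitter, all on the log2 scale so that configured
  effects translate into unbiased signal-log-ratio expectations.  The
  noise model is measurement noise only: between-donor biological
  variance, which in real cohorts shifts whole probe-sets coherently and
  inflates heterogeneous change-call rates, is deliberately absent so the
  filter's false-positive channel stays Bonferroni-bounded and recovery
  targets remain analytic;
* gene classes: *common* IFN genes induced in both non-baseline groups
  with the disease effect amplified relative to the vaccination effect
  (viral infection shows the same transcripts at markedly lower fold
  changes); *disease-specific* and *immunisation-specific* genes induced
  in one condition only; non-IFN differential genes; null genes; and
  near-background "absent" genes whose MM tracks PM;
* an annotation in which a fraction of genes own two probe-sets (to
  exercise the gene-level reassignment rule) and a reference gene list
  containing the IFN classes plus non-differential decoys.

Everything is driven by one integer seed: the same seed reproduces the
cohort bit-for-bit, and a per-sample RNG stream lets a single sample be
regenerated with its effects zeroed (a vaccine non-responder) without
disturbing any other draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .mas5_lite import ProbeLevelArray
from .reference_signature import Annotation, ReferenceList, build_reference

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "Cohort",
    "simulate_cohort",
    "simulate_pbmc_mixture",
    "simulate_pbmc_cohort",
    "make_nonresponder",
]

GROUPS = ("baseline", "day7", "disease")

CLASS_PREFIX = {
    "common_ifn": "CMN",
    "disease_specific": "DSP",
    "immunisation_specific": "ISP",
    "non_ifn_de": "NDE",
    "null": "NUL",
    "absent": "ABS",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated cohort (all log2 scale unless noted)."""

    n_baseline: int = 4
    n_day7: int = 4
    n_disease: int = 4
    n_common: int = 150
    n_disease_specific: int = 100
    n_immunisation_specific: int = 10
    n_non_ifn_de: int = 100
    n_null: int = 600
    n_absent: int = 40
    probes_per_set: int = 11
    base_mean: float = 7.0
    base_sd: float = 1.5
    common_fc_mean: float = 3.0  # day-7 effect of common genes
    common_fc_sd: float = 0.7
    disease_amplification: float = 1.4  # multiplies the common effect in disease
    disease_fc_mean: float = 2.5  # disease-specific genes, disease only
    disease_fc_sd: float = 0.7
    imm_fc_mean: float = 2.5  # immunisation-specific genes, day 7 only
    imm_fc_sd: float = 0.7
    non_ifn_fc_mean: float = 2.5  # non-IFN differential genes, disease only
    non_ifn_fc_sd: float = 0.7
    noise_sd: float = 0.4  # per-array measurement noise, drawn per probe
    probe_affinity_sd: float = 0.5  # per probe, fixed across arrays
    probe_noise_sd: float = 0.15  # residual per-probe jitter
    mm_frac: float = 0.3  # MM as a fraction of PM (linear scale)
    mm_noise_sd: float = 0.2  # log2 jitter on MM
    background_log2: float = 2.0  # absent-gene level
    two_probeset_frac: float = 0.10  # genes owning a second probe-set
    decoy_frac: float = 0.10  # extra reference genes drawn from the null class
    platform_id: str = "SIM-133P2"

    def validate(self) -> None:
        bad = []
        for name in ("base_sd", "common_fc_sd", "disease_fc_sd", "imm_fc_sd",
                     "non_ifn_fc_sd", "noise_sd", "probe_affinity_sd",
                     "probe_noise_sd", "mm_noise_sd"):
            if getattr(self, name) <= 0:
                bad.append(f"{name} must be > 0")
        for name in ("n_common", "n_disease_specific", "n_immunisation_specific",
                     "n_non_ifn_de", "n_null", "n_absent"):
            if getattr(self, name) < 0:
                bad.append(f"{name} must be >= 0")
        for name in ("n_baseline", "n_day7", "n_disease"):
            if getattr(self, name) < 1:
                bad.append(f"{name} must be >= 1")
        if self.probes_per_set < 3:
            bad.append("probes_per_set must be >= 3")
        if not (0 < self.mm_frac < 1):
            bad.append("mm_frac must be in (0, 1)")
        if bad:
            raise ValueError("invalid simulation config: " + "; ".join(bad))


@dataclass
class SimulationTruth:
    gene_class: Dict[str, str]
    effects: Dict[str, Dict[str, float]]  # gene -> group -> log2 effect
    probesets_of: Dict[str, List[str]]
    gene_of_probeset: Dict[str, str]
    zeroed_samples: Set[str] = field(default_factory=set)

    def probesets_of_class(self, cls: str) -> Set[str]:
        return {
            pid
            for g, c in self.gene_class.items()
            if c == cls
            for pid in self.probesets_of[g]
        }


@dataclass
class Cohort:
    groups: Dict[str, List[ProbeLevelArray]]
    truth: SimulationTruth
    annotation: Annotation
    reference: ReferenceList
    config: SimulationConfig
    seed: int

    @property
    def sample_ids(self) -> List[str]:
        return [a.sample_id for g in GROUPS for a in self.groups[g]]

    def group_of(self, sample_id: str) -> str:
        for g, arrays in self.groups.items():
            if any(a.sample_id == sample_id for a in arrays):
                return g
        raise KeyError(sample_id)


def _gene_names(config: SimulationConfig) -> List[Tuple[str, str]]:
    counts = {
        "common_ifn": config.n_common,
        "disease_specific": config.n_disease_specific,
        "immunisation_specific": config.n_immunisation_specific,
        "non_ifn_de": config.n_non_ifn_de,
        "null": config.n_null,
        "absent": config.n_absent,
    }
    out = []
    for cls, n in counts.items():
        for i in range(n):
            out.append((f"{CLASS_PREFIX[cls]}{i + 1:04d}", cls))
    return out


def simulate_cohort(
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
    zero_effect_samples: Iterable[str] = (),
) -> Cohort:
    """Generate the three-group probe-level cohort with its ground truth.

    ``zero_effect_samples`` regenerates the named samples with all effects
    set to zero while every random draw stays identical — the mechanism
    behind :func:`make_nonresponder`.
    """
    config = config or SimulationConfig()
    config.validate()
    zero_effect_samples = set(zero_effect_samples)

    genes = _gene_names(config)
    n_samples = config.n_baseline + config.n_day7 + config.n_disease
    root = np.random.SeedSequence(seed)
    structure_ss, *sample_ss = root.spawn(1 + n_samples)
    rng = np.random.default_rng(structure_ss)

    # --- gene-level structure -------------------------------------------
    gene_class: Dict[str, str] = dict(genes)
    base: Dict[str, float] = {}
    effects: Dict[str, Dict[str, float]] = {}
    for g, cls in genes:
        base[g] = (
            config.background_log2
            if cls == "absent"
            else float(rng.normal(config.base_mean, config.base_sd))
        )
        eff = {"baseline": 0.0, "day7": 0.0, "disease": 0.0}
        if cls == "common_ifn":
            day7 = float(rng.normal(config.common_fc_mean, config.common_fc_sd))
            eff["day7"] = day7
            eff["disease"] = day7 * config.disease_amplification
        elif cls == "disease_specific":
            eff["disease"] = float(rng.normal(config.disease_fc_mean, config.disease_fc_sd))
        elif cls == "immunisation_specific":
            eff["day7"] = float(rng.normal(config.imm_fc_mean, config.imm_fc_sd))
        elif cls == "non_ifn_de":
            eff["disease"] = float(rng.normal(config.non_ifn_fc_mean, config.non_ifn_fc_sd))
        effects[g] = eff

    # --- probe-set structure --------------------------------------------
    probesets_of: Dict[str, List[str]] = {}
    gene_of_probeset: Dict[str, str] = {}
    for g, cls in genes:
        n_sets = 2 if rng.random() < config.two_probeset_frac else 1
        pids = [f"{g}_s{k + 1}_at" for k in range(n_sets)]
        probesets_of[g] = pids
        for pid in pids:
            gene_of_probeset[pid] = g
    probeset_ids = [pid for g, _ in genes for pid in probesets_of[g]]
    affinities = {
        pid: rng.normal(0.0, config.probe_affinity_sd, size=config.probes_per_set)
        for pid in probeset_ids
    }

    # --- reference list and annotation ----------------------------------
    ifn_genes = [g for g, cls in genes if cls in
                 ("common_ifn", "disease_specific", "immunisation_specific")]
    null_genes = [g for g, cls in genes if cls == "null"]
    n_decoys = min(len(null_genes), int(round(config.decoy_frac * len(ifn_genes))))
    decoys = list(rng.choice(null_genes, size=n_decoys, replace=False)) if n_decoys else []
    # split so both provenance tags are exercised
    cut = max(1, len(ifn_genes) // 2)
    reference = build_reference(ifn_genes[:cut], ifn_genes[cut:] + [str(d) for d in decoys])
    annotation = Annotation(
        pd.DataFrame(
            {
                "probeset_id": probeset_ids,
                "gene_symbol": [gene_of_probeset[p] for p in probeset_ids],
                "platform_id": config.platform_id,
            }
        )
    )

    # --- per-sample probe intensities -----------------------------------
    sample_plan: List[Tuple[str, str]] = []
    for grp, n in (("baseline", config.n_baseline), ("day7", config.n_day7),
                   ("disease", config.n_disease)):
        prefix = {"baseline": "BL", "day7": "D7", "disease": "SLE"}[grp]
        for i in range(n):
            sample_plan.append((f"{prefix}_{i + 1:02d}", grp))
    unknown = zero_effect_samples - {s for s, _ in sample_plan}
    if unknown:
        raise ValueError(f"unknown samples to zero: {sorted(unknown)}")

    groups: Dict[str, List[ProbeLevelArray]] = {g: [] for g in GROUPS}
    n_ps = len(probeset_ids)
    for (sample_id, grp), ss in zip(sample_plan, sample_ss):
        srng = np.random.default_rng(ss)
        array_noise = srng.normal(0.0, config.noise_sd, size=(n_ps, config.probes_per_set))
        probe_noise = srng.normal(0.0, config.probe_noise_sd, size=(n_ps, config.probes_per_set))
        mm_eps = srng.normal(0.0, config.mm_noise_sd, size=(n_ps, config.probes_per_set))
        arr = ProbeLevelArray(sample_id=sample_id)
        zero_me = sample_id in zero_effect_samples
        k = 0
        for gi, (g, cls) in enumerate(genes):
            eff = 0.0 if zero_me else effects[g][grp]
            for pid in probesets_of[g]:
                log_pm = base[g] + eff + array_noise[k] + affinities[pid] + probe_noise[k]
                pm = 2.0 ** log_pm
                if cls == "absent":
                    mm = pm * 2.0 ** mm_eps[k]  # MM tracks PM: no discrimination signal
                else:
                    mm = config.mm_frac * pm * 2.0 ** mm_eps[k]
                arr.probesets[pid] = (pm, mm)
                k += 1
        groups[grp].append(arr)

    truth = SimulationTruth(
        gene_class=gene_class,
        effects=effects,
        probesets_of=probesets_of,
        gene_of_probeset=gene_of_probeset,
        zeroed_samples=set(zero_effect_samples),
    )
    return Cohort(
        groups=groups,
        truth=truth,
        annotation=annotation,
        reference=reference,
        config=config,
        seed=seed,
    )


def make_nonresponder(cohort: Cohort, sample_id: str) -> Cohort:
    """Return the cohort with one sample's effects zeroed (same noise draws).

    Applied to a baseline sample this is a no-op (baseline effects are
    already zero) apart from the truth record.
    """
    if sample_id not in cohort.sample_ids:
        raise ValueError(f"unknown sample {sample_id!r}")
    zeroed = set(cohort.truth.zeroed_samples) | {sample_id}
    import logging

    if cohort.group_of(sample_id) == "baseline":
        logging.getLogger(__name__).warning(
            "sample %s is a baseline sample; zeroing its effects is a no-op", sample_id
        )
    return simulate_cohort(cohort.config, cohort.seed, zero_effect_samples=zeroed)


# --------------------------------------------------------------------------
# PBMC mixtures
# --------------------------------------------------------------------------

def simulate_pbmc_mixture(
    celltype_profiles: pd.DataFrame,
    composition: Optional[pd.DataFrame] = None,
    n_samples: Optional[int] = None,
    noise_sd: float = 0.4,
    dirichlet_alpha: Optional[Sequence[float]] = None,
    concentration: float = 30.0,
    seed: int = 0,
    sample_prefix: str = "PBMC",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Mix cell-type expression profiles into heterogeneous samples.

    ``celltype_profiles``: log2 matrix, probe-sets x cell types.
    ``composition``: samples x cell types fractions (rows sum to 1); when
    omitted, ``n_samples`` rows are drawn from a Dirichlet whose mean is
    ``dirichlet_alpha`` (uniform by default) scaled by ``concentration``.
    Mixing is on the linear scale (transcripts add), then log-normal noise
    is applied and the result returned in log2 along with the fractions.
    """
    rng = np.random.default_rng(seed)
    celltypes = list(celltype_profiles.columns)
    if composition is None:
        if n_samples is None:
            raise ValueError("provide composition or n_samples")
        mean = (
            np.full(len(celltypes), 1.0 / len(celltypes))
            if dirichlet_alpha is None
            else np.asarray(dirichlet_alpha, dtype=float)
        )
        mean = mean / mean.sum()
        fracs = rng.dirichlet(mean * concentration, size=n_samples)
        composition = pd.DataFrame(
            fracs,
            index=[f"{sample_prefix}_{i + 1:02d}" for i in range(n_samples)],
            columns=celltypes,
        )
    else:
        composition = composition[celltypes].astype(float)
        sums = composition.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("composition fractions must sum to 1 per sample")
        if (composition < 0).any().any():
            raise ValueError("composition fractions must be non-negative")
    linear = 2.0 ** celltype_profiles.to_numpy(dtype=float)  # probesets x celltypes
    mix = linear @ composition.to_numpy(dtype=float).T  # probesets x samples
    if noise_sd > 0:
        mix = mix * 2.0 ** rng.normal(0.0, noise_sd, size=mix.shape)
    matrix = pd.DataFrame(
        np.log2(mix), index=celltype_profiles.index, columns=composition.index
    )
    return matrix, composition


def _celltype_profiles(
    cohort_truth: SimulationTruth,
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator,
    celltype_offsets: Mapping[str, np.ndarray],
    base: Mapping[str, float],
    responders: Sequence[str],
) -> pd.DataFrame:
    pids = sorted(cohort_truth.gene_of_probeset)
    data = {}
    for ct, offs in celltype_offsets.items():
        col = []
        for i, pid in enumerate(pids):
            g = cohort_truth.gene_of_probeset[pid]
            eff = cohort_truth.effects[g][condition] if ct in responders else 0.0
            col.append(base[g] + offs[i] + eff)
        data[ct] = col
    return pd.DataFrame(data, index=pids)


def simulate_pbmc_cohort(
    cohort: Cohort,
    n_case: int = 10,
    n_control: int = 10,
    condition: str = "disease",
    responders: Sequence[str] = ("monocyte", "tcell"),
    celltype_mean_fracs: Mapping[str, float] = None,
    celltype_offset_sd: float = 2.0,
    concentration: float = 30.0,
    noise_sd: float = 0.4,
    seed: int = 0,
    zero_effect_cases: Iterable[str] = (),
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """PBMC validation cohort built on a simulated sorted-cell study.

    Cell-type profiles share the cohort's gene structure; case samples mix
    profiles carrying the chosen condition's effects in the responding
    cell types, controls mix unstimulated profiles, and every sample gets
    its own Dirichlet-drawn composition.  Returns the log2 expression
    matrix and a sample -> "case"/"control" label map.  Samples named in
    ``zero_effect_cases`` are generated as non-responders: labelled case
    but mixed from unstimulated profiles.
    """
    if celltype_mean_fracs is None:
        celltype_mean_fracs = {"monocyte": 0.2, "tcell": 0.5, "bcell": 0.15, "nk": 0.15}
    rng = np.random.default_rng(np.random.SeedSequence((cohort.seed, seed, 0x9E3779B9)))
    celltypes = list(celltype_mean_fracs)
    pids = sorted(cohort.truth.gene_of_probeset)
    genes = sorted({cohort.truth.gene_of_probeset[p] for p in pids})
    base = {
        g: (cohort.config.background_log2 if cohort.truth.gene_class[g] == "absent"
            else cohort.config.base_mean)
        for g in genes
    }
    offsets = {ct: rng.normal(0.0, celltype_offset_sd, size=len(pids)) for ct in celltypes}
    prof_ctrl = _celltype_profiles(
        cohort.truth, cohort.config, "baseline", rng, offsets, base, responders
    )
    prof_case = _celltype_profiles(
        cohort.truth, cohort.config, condition, rng, offsets, base, responders
    )
    mean = np.array([celltype_mean_fracs[ct] for ct in celltypes])
    mean = mean / mean.sum()

    zero_effect_cases = set(zero_effect_cases)
    labels: Dict[str, str] = {}
    cols = {}
    plan = [(f"PBMC_SLE_{i + 1:02d}", "case") for i in range(n_case)] + [
        (f"PBMC_ND_{i + 1:02d}", "control") for i in range(n_control)
    ]
    unknown = zero_effect_cases - {s for s, lab in plan if lab == "case"}
    if unknown:
        raise ValueError(f"unknown case samples: {sorted(unknown)}")
    linear_ctrl = 2.0 ** prof_ctrl.to_numpy()
    linear_case = 2.0 ** prof_case.to_numpy()
    for sample, lab in plan:
        frac = rng.dirichlet(mean * concentration)
        source = linear_ctrl if (lab == "control" or sample in zero_effect_cases) else linear_case
        mix = source @ frac
        mix = mix * 2.0 ** rng.normal(0.0, noise_sd, size=mix.shape)
        cols[sample] = np.log2(mix)
        labels[sample] = lab
    matrix = pd.DataFrame(cols, index=pids)
    return matrix, labels
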