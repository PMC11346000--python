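"""Synthetic flow-cytometry sample pairs and cohorts with ground truth.

Dissociated FFPE breast-tumour samples are mixtures of nucleus populations:
cancer nuclei (larger FSC/SSC, CK-positive, a fraction Ki67-positive),
lymphocyte nuclei (smaller — roughly 0.4x the cancer scatter means,
CK-negative), rare normal epithelial nuclei (mixed CK), sub-2n debris and
>=4n aggregates.  The DNA-dye histogram is 2n-dominant with an S-phase
plateau and a 4n (G2/M) peak.  This module draws such mixtures, builds the
isotype-control twin (identical FSC/SSC/DNA draws; antibody channels
replaced by background), and returns per-event ground truth for scoring.

Channel scales are arbitrary units: the 2n DAPI peak sits at 100 (CV 5%),
cancer scatter at (600, 500), and positive antibody signals are lognormals
separated from background by more than 10x in median, so default mixtures
are cleanly separable; overlap stress tests can supply their own specs.
Every public operation takes an explicit integer seed and is bit
reproducible.

The distributions emulate the *statistical structure* the gating scheme
assumes; they are conventions, not estimates of any real instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import EventTable, SamplePair

__all__ = [
    "DNA_2N_MEAN",
    "CHANNEL_NAMES",
    "PopulationSpec",
    "CohortSpec",
    "default_tumor_populations",
    "lymphnode_populations",
    "uniform_background_pair_spec",
    "simulate_pair",
    "simulate_lymphnode",
    "simulate_cohort",
]

#: DNA-channel position of the diploid (2n) peak, arbitrary units.
DNA_2N_MEAN = 100.0

#: Default instrument channel names by role.
CHANNEL_NAMES = {"FSC": "FSC-A", "SSC": "SSC-A", "DNA": "DAPI-A",
                 "CK": "FITC-A", "KI67": "APC-A"}

# Background (isotype / unstained) lognormal parameters, shared default.
_BG = {"median": 8.0, "sigma": 0.6}
_POS_CK = {"median": 150.0, "sigma": 0.5}
_POS_KI67 = {"median": 150.0, "sigma": 0.5}


@dataclass(frozen=True)
class PopulationSpec:
    """One nucleus population of a simulated sample.

    ``dna`` kinds: ``cycling`` (2n Gaussian with ``cv``, ``s_frac`` uniform
    S-phase plateau, ``g2_frac`` 4n Gaussian), ``debris`` (sub-2n uniform),
    ``aggregate`` (2- and 3-nucleus clumps, i.e. 4n/6n).  ``ki67_p`` is the
    population's true Ki67-positive fraction; negative cells draw their
    Ki67 channel from the same background distribution as the isotype twin,
    so percentile-cutoff algebra is exact by construction.
    """

    name: str
    fraction: float
    fsc_ssc_mean: tuple
    fsc_ssc_cov: tuple            # 2x2 nested tuples
    dna_kind: str = "cycling"
    dna_cv: float = 0.05
    s_frac: float = 0.08
    g2_frac: float = 0.07
    ck_positive_frac: float = 0.0
    ki67_p: float = 0.0
    ck_pos: dict = field(default_factory=lambda: dict(_POS_CK))
    ki67_pos: dict = field(default_factory=lambda: dict(_POS_KI67))
    background: dict = field(default_factory=lambda: dict(_BG))

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError(f"{self.name}: fraction must be in [0, 1]")
        if not 0 <= self.ki67_p <= 1:
            raise ValueError(f"{self.name}: ki67_p must be in [0, 1]")
        if self.dna_kind not in ("cycling", "debris", "aggregate"):
            raise ValueError(f"{self.name}: unknown dna_kind {self.dna_kind!r}")


def default_tumor_populations(true_li: float = 0.30) -> list[PopulationSpec]:
    """Default breast-tumour mixture; ``true_li`` is the cancer-cell
    Ki67-positive fraction (the quantity the assay estimates)."""
    return [
        PopulationSpec("cancer", 0.55, (600.0, 500.0),
                       ((80.0**2, 0.5 * 80 * 70), (0.5 * 80 * 70, 70.0**2)),
                       ck_positive_frac=1.0, ki67_p=true_li),
        PopulationSpec("lymphocyte", 0.25, (240.0, 200.0),
                       ((40.0**2, 0.3 * 40 * 35), (0.3 * 40 * 35, 35.0**2)),
                       ck_positive_frac=0.0, ki67_p=0.0),
        PopulationSpec("normal_epithelial", 0.03, (430.0, 360.0),
                       ((60.0**2, 0.3 * 60 * 55), (0.3 * 60 * 55, 55.0**2)),
                       ck_positive_frac=0.5, ki67_p=0.02),
        PopulationSpec("debris", 0.12, (120.0, 90.0),
                       ((60.0**2, 0.0), (0.0, 50.0**2)),
                       dna_kind="debris"),
        PopulationSpec("aggregate", 0.05, (900.0, 780.0),
                       ((120.0**2, 0.4 * 120 * 110), (0.4 * 120 * 110, 110.0**2)),
                       dna_kind="aggregate", ck_positive_frac=1.0,
                       ki67_p=true_li),
    ]


def lymphnode_populations() -> list[PopulationSpec]:
    """Normal lymph-node section: lymphocyte nuclei plus debris only."""
    return [
        PopulationSpec("lymphocyte", 0.85, (240.0, 200.0),
                       ((40.0**2, 0.3 * 40 * 35), (0.3 * 40 * 35, 35.0**2))),
        PopulationSpec("debris", 0.15, (120.0, 90.0),
                       ((60.0**2, 0.0), (0.0, 50.0**2)), dna_kind="debris"),
    ]


def uniform_background_pair_spec(p: float) -> list[PopulationSpec]:
    """Single-population spec for cutoff-calibration experiments: negatives
    distributed exactly as the control, a fraction ``p`` truly positive."""
    return [
        PopulationSpec("cancer", 1.0, (600.0, 500.0),
                       ((80.0**2, 0.0), (0.0, 70.0**2)),
                       ck_positive_frac=1.0, ki67_p=p),
    ]


def _lognormal(rng, median: float, sigma: float, n: int) -> np.ndarray:
    return rng.lognormal(mean=np.log(median), sigma=sigma, size=n)


def _draw_population(rng, spec: PopulationSpec, n: int):
    mean = np.asarray(spec.fsc_ssc_mean, dtype=float)
    cov = np.asarray(spec.fsc_ssc_cov, dtype=float)
    scatter = rng.multivariate_normal(mean, cov, size=n)
    np.clip(scatter, 0.0, None, out=scatter)

    if spec.dna_kind == "cycling":
        u = rng.uniform(size=n)
        dna = rng.normal(DNA_2N_MEAN, spec.dna_cv * DNA_2N_MEAN, size=n)
        s_phase = u < spec.s_frac
        g2 = (u >= spec.s_frac) & (u < spec.s_frac + spec.g2_frac)
        dna[s_phase] = rng.uniform(DNA_2N_MEAN * 1.05, DNA_2N_MEAN * 1.95,
                                   size=int(s_phase.sum()))
        dna[g2] = rng.normal(2 * DNA_2N_MEAN, 2 * spec.dna_cv * DNA_2N_MEAN,
                             size=int(g2.sum()))
    elif spec.dna_kind == "debris":
        dna = rng.uniform(0.05 * DNA_2N_MEAN, 0.75 * DNA_2N_MEAN, size=n)
    else:  # aggregate: 2- or 3-nucleus clumps
        k = rng.choice([2, 3], size=n, p=[0.8, 0.2])
        dna = rng.normal(k * 2 * DNA_2N_MEAN, 2 * spec.dna_cv * DNA_2N_MEAN)
    np.clip(dna, 0.0, None, out=dna)

    bg = spec.background
    ck = _lognormal(rng, bg["median"], bg["sigma"], n)
    ck_pos_mask = rng.uniform(size=n) < spec.ck_positive_frac
    n_ck = int(ck_pos_mask.sum())
    if n_ck:
        ck[ck_pos_mask] = _lognormal(rng, spec.ck_pos["median"],
                                     spec.ck_pos["sigma"], n_ck)

    ki67 = _lognormal(rng, bg["median"], bg["sigma"], n)
    ki67_state = rng.uniform(size=n) < spec.ki67_p
    n_pos = int(ki67_state.sum())
    if n_pos:
        ki67[ki67_state] = _lognormal(rng, spec.ki67_pos["median"],
                                      spec.ki67_pos["sigma"], n_pos)

    control_ck = _lognormal(rng, bg["median"], bg["sigma"], n)
    control_ki67 = _lognormal(rng, bg["median"], bg["sigma"], n)
    return scatter, dna, ck, ki67, control_ck, control_ki67, ck_pos_mask, ki67_state


def simulate_pair(populations: list[PopulationSpec], n_events: int, seed: int,
                  pair_id: str = "synthetic"):
    """Draw a stained/control sample pair plus per-event ground truth.

    The isotype-control twin shares the FSC/SSC/DNA draws of the stained
    member and replaces the antibody channels (CK, Ki67) with background
    draws.  Returns ``(SamplePair, truth)`` where ``truth`` is a DataFrame
    with columns ``population`` and ``ki67_positive`` aligned to the event
    order of both tables.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    fractions = np.array([p.fraction for p in populations], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"population fractions sum to {fractions.sum()}, not 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_events, fractions)

    blocks, truth_pop, truth_ki67 = [], [], []
    for spec, n in zip(populations, counts):
        if n == 0:
            continue
        scatter, dna, ck, ki67, c_ck, c_ki67, _, ki67_state = \
            _draw_population(rng, spec, int(n))
        blocks.append((scatter, dna, ck, ki67, c_ck, c_ki67))
        truth_pop.append(np.full(n, spec.name, dtype=object))
        truth_ki67.append(ki67_state)

    scatter = np.vstack([b[0] for b in blocks])
    dna = np.concatenate([b[1] for b in blocks])
    ck = np.concatenate([b[2] for b in blocks])
    ki67 = np.concatenate([b[3] for b in blocks])
    c_ck = np.concatenate([b[4] for b in blocks])
    c_ki67 = np.concatenate([b[5] for b in blocks])
    pop = np.concatenate(truth_pop)
    state = np.concatenate(truth_ki67)

    perm = rng.permutation(len(dna))
    names = CHANNEL_NAMES

    def table(ck_v, ki67_v, stain):
        df = pd.DataFrame({
            names["FSC"]: scatter[perm, 0], names["SSC"]: scatter[perm, 1],
            names["DNA"]: dna[perm], names["CK"]: ck_v[perm],
            names["KI67"]: ki67_v[perm],
        })
        return EventTable(data=df, channel_map=dict(names),
                          sample_id=f"{pair_id}_{stain}", stain=stain)

    pair = SamplePair(stained=table(ck, ki67, "antibody"),
                      control=table(c_ck, c_ki67, "isotype_control"),
                      pair_id=pair_id)
    truth = pd.DataFrame({"population": pop[perm], "ki67_positive": state[perm]})
    return pair, truth


def simulate_lymphnode(n_events: int, seed: int,
                       pair_id: str = "lymphnode") -> SamplePair:
    """Normal lymph-node sample pair (lymphocytes + debris, no Ki67)."""
    pair, _ = simulate_pair(lymphnode_populations(), n_events, seed, pair_id)
    return pair


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic clinical cohort.

    ``hotspot_multiplier`` and ``observer_noise_sd`` emulate the pathology
    reference labelling index: a pathologist scores the hottest region, so
    the reference runs above the whole-section truth, with observer noise
    on top.
    """

    n_cases: int = 30
    li_low: float = 5.0            # percent
    li_high: float = 50.0          # percent
    hotspot_multiplier: float = 1.4
    observer_noise_sd: float = 3.0  # percentage points
    events_per_case: int = 20_000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.hotspot_multiplier < 1:
            raise ValueError("hotspot_multiplier must be >= 1")


def simulate_cohort(spec: CohortSpec):
    """Simulate a cohort of sample pairs with true and pathology-style LI.

    Returns a list of ``(SamplePair, true_li_percent, pathology_li_percent)``
    tuples.  Per-case seeds derive deterministically from the master seed.
    """
    rng = np.random.default_rng(spec.master_seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=spec.n_cases)
    out = []
    for i, seed in enumerate(case_seeds):
        true_li = float(rng.uniform(spec.li_low, spec.li_high))
        path_li = float(np.clip(
            true_li * spec.hotspot_multiplier
            + rng.normal(0.0, spec.observer_noise_sd), 0.0, 100.0))
        pops = default_tumor_populations(true_li=true_li / 100.0)
        pair, _ = simulate_pair(pops, spec.events_per_case, int(seed),
                                pair_id=f"case{i + 1:02d}")
        out.append((pair, true_li, path_li))
    return out
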