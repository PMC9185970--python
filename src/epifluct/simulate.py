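"""Synthetic longitudinal methylation data with known ground truth.

The real study design being emulated is small and dense: a handful of
individuals, each sampled repeatedly over weeks to months, with two sample
types per draw — a mixed cell population (PBMC-like) whose composition drifts
from day to day, and a purified population (monocyte-like).  The individual-
level data behind such designs are typically private, so every analysis in
this package is exercised against matrices produced here, with a
:class:`SimulationTruth` table for parameter-recovery tests.

Generative model, per probe p and sample s = (individual, sample type, day t):

    mu_ps   = sum_k w_ks * ref_pk                  (cell-mixture expectation)
    x_pt    = phi^gap * x_p,t-1 + sqrt(1-phi^(2*gap)) * sd_p * eps   (AR(1), logit scale)
    beta_ps = clip( invlogit(logit(mu_ps) + x_pt) + N(0, noise_sd[design type]), 0, 1 )

The AR(1) perturbation lives on the logit scale so betas stay in (0, 1)
before measurement noise; ``phi^gap`` makes the autocorrelation decay with
the actual day gap between collections.  Measurement noise depends on the
Infinium design type (type II chemistry is noisier than type I).

Clocks can be generated with an inverse coupling between coefficient
magnitude and per-CpG fluctuation SD — the defensive pattern real clocks
exhibit, where noisy CpGs receive small weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit as _logit

from .clocks import ClockDefinition, compute_epigenetic_age
from .containers import SAMPLE_SHEET_COLUMNS, BetaMatrix
from .errors import InvalidArgumentError, MissingProbeError

_EPS = 1e-6

DEFAULT_PROBE_NOISE = {"I": 0.01, "II": 0.025}

DEFAULT_CATEGORY_PROBS = {
    "design_type": {"I": 0.28, "II": 0.72},
    "island_relation": {"Island": 0.31, "Shore": 0.23, "Shelf": 0.10, "OpenSea": 0.36},
    "genic_category": {"Promoter": 0.40, "Body": 0.35, "3'UTR": 0.05, "Intergenic": 0.20},
}

#: log-scale parameters of the prior on per-CpG logit-beta fluctuation SD
_SD_LOG_MU = np.log(0.12)
_SD_LOG_SIGMA = 0.6


# ---------------------------------------------------------------------------
# study design


@dataclass(frozen=True)
class StudyDesign:
    """Who was sampled, what was collected, and when.

    ``collection_days`` is the shared, strictly increasing list of integer
    day indices at which every (individual, sample type) series is observed.
    """

    individuals: tuple[str, ...]
    sample_types: tuple[str, ...]
    collection_days: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        days = self.collection_days
        if len(days) < 2:
            raise InvalidArgumentError("a design needs at least 2 time points")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise InvalidArgumentError("collection_days must be strictly increasing")
        if not self.individuals or not self.sample_types:
            raise InvalidArgumentError("need at least one individual and one sample type")

    @property
    def n_timepoints(self) -> int:
        return len(self.collection_days)

    @property
    def n_samples(self) -> int:
        return len(self.individuals) * len(self.sample_types) * self.n_timepoints

    def sample_sheet(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": f"{ind}_{st}_d{day:03d}",
                "individual": ind,
                "sample_type": st,
                "day": day,
            }
            for ind in self.individuals
            for st in self.sample_types
            for day in self.collection_days
        ]
        return pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS)


def generate_study_design(
    n_individuals: int,
    n_sample_types: int,
    n_timepoints: int,
    day_spacing="mixed",
    seed: int = 0,
) -> StudyDesign:
    """Build a longitudinal design of ``n_individuals × n_sample_types × n_timepoints`` samples.

    ``day_spacing`` controls the gaps between consecutive collection days:
    a positive integer gives a constant gap; a sequence gives explicit gaps
    (cycled as needed); the default ``"mixed"`` draws gaps from {1, 1, 2, 3,
    4, 5, 7} days so that some consecutive collections are exactly one day
    apart (the pairs "daily change" is computed from) while the series still
    spans months.
    """
    for name, n in [
        ("n_individuals", n_individuals),
        ("n_sample_types", n_sample_types),
        ("n_timepoints", n_timepoints),
    ]:
        if not isinstance(n, (int, np.integer)) or n < 1:
            raise InvalidArgumentError(f"{name} must be a positive integer, got {n!r}")
    if n_timepoints < 2:
        raise InvalidArgumentError("n_timepoints must be >= 2")
    rng = np.random.default_rng(seed)
    if isinstance(day_spacing, str):
        if day_spacing != "mixed":
            raise InvalidArgumentError(f"unknown day_spacing spec {day_spacing!r}")
        gaps = rng.choice([1, 1, 2, 3, 4, 5, 7], size=n_timepoints - 1)
    elif isinstance(day_spacing, (int, np.integer)):
        if day_spacing < 1:
            raise InvalidArgumentError("constant day gap must be >= 1")
        gaps = np.full(n_timepoints - 1, int(day_spacing))
    else:
        gaps = np.array(
            [int(day_spacing[i % len(day_spacing)]) for i in range(n_timepoints - 1)]
        )
        if (gaps < 1).any():
            raise InvalidArgumentError("all day gaps must be positive integers")
    days = tuple(int(d) for d in np.concatenate([[0], np.cumsum(gaps)]))
    individuals = tuple(f"person_{chr(ord('A') + i)}" for i in range(n_individuals))
    default_types = ["PBMC", "monocyte"]
    sample_types = tuple(
        default_types[i] if i < len(default_types) else f"type_{i}"
        for i in range(n_sample_types)
    )
    return StudyDesign(individuals, sample_types, days, seed=seed)


# ---------------------------------------------------------------------------
# clocks


class GeneratedClock(NamedTuple):
    """A synthetic clock plus the per-CpG fluctuation SDs assigned to it."""

    clock: ClockDefinition
    fluctuation_sd: pd.Series  # logit-scale AR(1) stationary SD per clock CpG


def _draw_coefficients(coef_spec, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(coef_spec, (int, float)):
        return np.full(n, float(coef_spec))
    kind = coef_spec[0]
    if kind == "constant":
        return np.full(n, float(coef_spec[1]))
    if kind == "normal":
        _, mu, sigma = coef_spec
        return rng.normal(float(mu), float(sigma), size=n)
    if kind == "uniform":
        _, lo, hi = coef_spec
        return rng.uniform(float(lo), float(hi), size=n)
    raise InvalidArgumentError(f"unknown coefficient spec {coef_spec!r}")


def probe_universe(n_probes: int) -> list[str]:
    """Opaque synthetic probe ids; clock CpGs are the first ``n`` of them."""
    return [f"cg{i:08d}" for i in range(n_probes)]


def generate_clock(
    n_cpgs: int,
    intercept: float,
    coef_spec,
    transform="identity",
    coupling: float = 0.0,
    seed: int = 0,
    name: str | None = None,
    cpg_offset: int = 0,
    center_age: float | None = None,
) -> GeneratedClock:
    """Generate a synthetic linear clock over ``n_cpgs`` consecutive probes
    of the shared universe, starting at ``cpg_offset``.

    ``coupling`` in [0, 1] sets the strength of the inverse relationship
    between |coefficient| and the CpG's assigned fluctuation SD: a Gaussian
    copula with correlation ``-coupling`` pairs coefficient magnitudes with
    SDs by rank, preserving both marginals. With coupling 0 the two are
    independent; with coupling > 0 their Spearman correlation is negative.

    ``transform`` is ``"identity"``, ``"horvath"`` or ``("horvath", adult_age)``.
    When ``center_age`` is given, the intercept argument is replaced by the
    value that makes a flat beta-0.5 profile read ``center_age`` years, so
    randomly drawn panels stay on a plausible human age scale.
    """
    if not isinstance(n_cpgs, (int, np.integer)) or n_cpgs < 1:
        raise InvalidArgumentError(f"n_cpgs must be a positive integer, got {n_cpgs!r}")
    if not 0.0 <= coupling <= 1.0:
        raise InvalidArgumentError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cpg_ids = [f"cg{i:08d}" for i in range(cpg_offset, cpg_offset + n_cpgs)]

    coefs = _draw_coefficients(coef_spec, n_cpgs, rng)
    # Gaussian copula: rank-pair |coef| with fluctuation SD at correlation -coupling
    z1 = rng.standard_normal(n_cpgs)
    z2 = -coupling * z1 + np.sqrt(max(0.0, 1.0 - coupling**2)) * rng.standard_normal(n_cpgs)
    sds = np.exp(_SD_LOG_MU + _SD_LOG_SIGMA * z2)
    # pair sorted |coef| magnitudes against the ranks of z1
    order_mag = np.sort(np.abs(coefs))
    ranks_z1 = np.argsort(np.argsort(z1))
    magnitudes = order_mag[ranks_z1]
    signs = np.sign(coefs)
    signs[signs == 0] = 1.0
    rng.shuffle(signs)
    coefs = signs * magnitudes

    if isinstance(transform, (tuple, list)):
        transform_name, adult_age = transform[0], float(transform[1])
    else:
        transform_name, adult_age = transform, 20.0
    if center_age is not None:
        # choose the intercept so an all-0.5 beta profile reads center_age:
        # keeps randomly drawn coefficient panels on a human age scale
        from .clocks import forward_transform

        target = (
            forward_transform(center_age, adult_age)
            if transform_name == "horvath"
            else float(center_age)
        )
        intercept = target - 0.5 * float(coefs.sum())
    clock = ClockDefinition(
        name=name or f"synthetic_clock_s{seed}",
        intercept=float(intercept),
        coefficients=dict(zip(cpg_ids, coefs.tolist())),
        transform=transform_name,
        adult_age=adult_age,
    )
    return GeneratedClock(clock, pd.Series(sds, index=cpg_ids, name="fluctuation_sd"))


# ---------------------------------------------------------------------------
# cell-type references


class CellReferences(NamedTuple):
    """Reference beta profiles (probes × cell types) and the discriminating probes."""

    profiles: pd.DataFrame
    discriminating: list[str]


def generate_cell_references(
    n_cell_types: int,
    n_probes: int,
    separation: float,
    seed: int = 0,
) -> CellReferences:
    """Reference profiles whose discriminating probes differ by >= ``separation``.

    Roughly 30% of probes (at least ``n_cell_types``) are discriminating: on
    each, the cell types are spread evenly over an interval of width exactly
    ``separation`` in a per-probe random order. The remaining probes share a
    common baseline across cell types.
    """
    if n_cell_types < 2:
        raise InvalidArgumentError("need at least 2 cell types")
    if not 0.0 < separation <= 1.0:
        raise InvalidArgumentError("separation must be in (0, 1]")
    rng = np.random.default_rng(seed)
    probes = probe_universe(n_probes)
    n_disc = max(n_cell_types, int(round(0.3 * n_probes)))
    n_disc = min(n_disc, n_probes)
    values = np.empty((n_probes, n_cell_types))
    baseline = rng.uniform(0.05, 0.95, size=n_probes)
    values[:] = baseline[:, None]
    spread = np.linspace(0.0, separation, n_cell_types)
    for i in range(n_disc):
        low = rng.uniform(0.0, 1.0 - separation)
        values[i] = low + rng.permutation(spread)
    cell_types = [f"cell_{chr(ord('A') + k)}" for k in range(n_cell_types)]
    profiles = pd.DataFrame(values, index=probes, columns=cell_types)
    return CellReferences(profiles, probes[:n_disc])


# ---------------------------------------------------------------------------
# longitudinal betas


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated beta matrix, for recovery tests."""

    true_cell_proportions: pd.DataFrame  # samples × cell types, rows sum to 1
    true_latent_age_signal: pd.Series  # noiseless mixture age per sample, years
    baseline_beta: pd.Series  # per-probe mean expected beta
    fluctuation_sd: pd.Series  # per-probe logit-scale AR(1) stationary SD
    ar1_coefficient: float
    probe_noise_sd: dict[str, float]

    def __post_init__(self) -> None:
        sums = self.true_cell_proportions.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise InvalidArgumentError("true proportions must sum to 1 per sample")
        b = self.baseline_beta.to_numpy(dtype=float)
        if b.size and (b.min() < 0 or b.max() > 1):
            raise InvalidArgumentError("baseline betas must lie in [0, 1]")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise InvalidArgumentError("AR(1) coefficient must be in [0, 1)")


def _default_mixing(design: StudyDesign, n_cell_types: int) -> dict:
    """Mixed first sample type with day-to-day jitter; later types purified.

    The first sample type is a composition-drifting mixture (PBMC-like); each
    subsequent sample type is a fixed vertex on one cell type (monocyte-like).
    """
    base = 2.0 ** -np.arange(n_cell_types)
    base /= base.sum()
    mixing: dict[str, dict] = {}
    for i, st in enumerate(design.sample_types):
        if i == 0:
            mixing[st] = {"base": base, "jitter_sd": 0.3}
        else:
            vertex = np.zeros(n_cell_types)
            vertex[min(i, n_cell_types - 1)] = 1.0
            mixing[st] = {"base": vertex, "jitter_sd": 0.0}
    return mixing


def generate_longitudinal_betas(
    design: StudyDesign,
    clock: GeneratedClock | ClockDefinition | None,
    references: CellReferences | pd.DataFrame,
    mixing: dict | None = None,
    fluctuation: dict | None = None,
    probe_noise: dict[str, float] | None = None,
    annotations: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[BetaMatrix, SimulationTruth]:
    """Simulate a probes × samples beta matrix under the documented model.

    Parameters
    ----------
    design:
        The study layout (who, which sample types, which days).
    clock:
        Optional clock whose CpGs must be contained in the reference probe
        set; a :class:`GeneratedClock` supplies per-CpG fluctuation SDs.
    references:
        Per-cell-type beta profiles defining the probe universe.
    mixing:
        Per-sample-type dict ``{"base": weights, "jitter_sd": float}``; the
        day-to-day proportions are a logistic-normal jitter around ``base``.
        Default: first sample type mixed with drift, the rest purified.
    fluctuation:
        ``{"ar1": phi, "sd": per-probe Series or scalar}``; probes without an
        entry draw their SD from the generator's lognormal prior. Default
        phi = 0.5. ``sd`` may be 0 for a fluctuation-free simulation.
    probe_noise:
        Measurement noise SD per design type, e.g. ``{"I": 0.01, "II": 0.025}``.
    annotations:
        Probe annotation table assigning design types; generated with default
        category frequencies when omitted.
    """
    profiles = references.profiles if isinstance(references, CellReferences) else references
    probes = list(profiles.index)
    n_probes = len(probes)
    cell_types = list(profiles.columns)
    n_cell = len(cell_types)

    clock_sds = None
    clock_def = None
    if isinstance(clock, GeneratedClock):
        clock_def, clock_sds = clock.clock, clock.fluctuation_sd
    elif clock is not None:
        clock_def = clock
    if clock_def is not None:
        missing = [c for c in clock_def.cpg_ids if c not in profiles.index]
        if missing:
            raise MissingProbeError(missing, context="clock CpGs not in probe universe")

    probe_noise = dict(DEFAULT_PROBE_NOISE if probe_noise is None else probe_noise)
    if any(v < 0 for v in probe_noise.values()):
        raise InvalidArgumentError("probe noise SDs must be >= 0")
    fluctuation = dict(fluctuation or {})
    phi = float(fluctuation.get("ar1", 0.5))
    if not 0.0 <= phi < 1.0:
        raise InvalidArgumentError("AR(1) coefficient must be in [0, 1)")

    rng = np.random.default_rng(seed)

    # per-probe fluctuation SD (logit scale)
    sd_spec = fluctuation.get("sd", None)
    sds = pd.Series(
        np.exp(_SD_LOG_MU + _SD_LOG_SIGMA * rng.standard_normal(n_probes)), index=probes
    )
    if clock_sds is not None:
        sds.loc[clock_sds.index] = clock_sds
    if sd_spec is not None:
        if np.isscalar(sd_spec):
            sds[:] = float(sd_spec)
        else:
            sds.loc[sd_spec.index] = sd_spec
    if (sds < 0).any():
        raise InvalidArgumentError("fluctuation SDs must be >= 0")

    if annotations is None:
        annotations = generate_annotations(probes, seed=int(rng.integers(2**31)))
    design_type = annotations.set_index("probe_id")["design_type"].reindex(probes)
    noise_sd = design_type.map(probe_noise).to_numpy(dtype=float)

    mixing = mixing if mixing is not None else _default_mixing(design, n_cell)

    sheet = design.sample_sheet()
    days = np.array(design.collection_days)
    gaps = np.diff(days)
    n_t = design.n_timepoints

    ref_arr = profiles.to_numpy(dtype=float)
    sd_arr = sds.to_numpy(dtype=float)

    all_cols: dict[str, np.ndarray] = {}
    prop_rows = []
    for ind in design.individuals:
        for st in design.sample_types:
            spec = mixing[st]
            base = np.asarray(spec["base"], dtype=float)
            if base.shape != (n_cell,) or (base < 0).any():
                raise InvalidArgumentError(
                    f"mixing base for {st!r} must be {n_cell} nonnegative weights"
                )
            base = base / base.sum()
            jitter = float(spec.get("jitter_sd", 0.0))

            # day-to-day cell proportions (logistic-normal jitter around base)
            if jitter > 0:
                active = base > 0
                logw = np.full((n_t, n_cell), -np.inf)
                logw[:, active] = np.log(base[active]) + jitter * rng.standard_normal(
                    (n_t, active.sum())
                )
                w = np.exp(logw - logw.max(axis=1, keepdims=True))
                w /= w.sum(axis=1, keepdims=True)
            else:
                w = np.tile(base, (n_t, 1))

            mu = ref_arr @ w.T  # probes × timepoints

            # AR(1) on the logit scale, gap-aware, stationary SD = sd_arr
            x = np.zeros((n_probes, n_t))
            if (sd_arr > 0).any():
                x[:, 0] = sd_arr * rng.standard_normal(n_probes)
                for t in range(1, n_t):
                    decay = phi ** gaps[t - 1]
                    innov_sd = sd_arr * np.sqrt(1.0 - decay**2)
                    x[:, t] = decay * x[:, t - 1] + innov_sd * rng.standard_normal(n_probes)

            mu_c = np.clip(mu, _EPS, 1.0 - _EPS)
            shifted = expit(_logit(mu_c) + x)
            # keep the mixture identity exact where the temporal term is zero
            shifted = np.where(x == 0.0, mu, shifted)
            noise = noise_sd[:, None] * rng.standard_normal((n_probes, n_t))
            noise[noise_sd == 0.0, :] = 0.0
            betas = np.clip(shifted + noise, 0.0, 1.0)

            for t, day in enumerate(days):
                sid = f"{ind}_{st}_d{day:03d}"
                all_cols[sid] = betas[:, t]
                prop_rows.append(pd.Series(w[t], index=cell_types, name=sid))

    values = pd.DataFrame(all_cols, index=probes).loc[:, sheet["sample_id"]]
    matrix = BetaMatrix(values=values, samples=sheet, normalization="raw")

    proportions = pd.DataFrame(prop_rows).loc[sheet["sample_id"]]
    proportions.index.name = "sample_id"

    # noiseless mixture age: what the clock would read off the pure mixture
    if clock_def is not None:
        mixture_only = matrix.with_values(
            pd.DataFrame(
                ref_arr @ proportions.to_numpy().T, index=probes, columns=sheet["sample_id"]
            )
        )
        latent = compute_epigenetic_age(mixture_only, clock_def).set_index("sample_id")[
            "epigenetic_age"
        ]
    else:
        latent = pd.Series(0.0, index=pd.Index(sheet["sample_id"], name="sample_id"))
    latent.name = "latent_age_signal"

    baseline = pd.Series(
        np.clip((ref_arr @ proportions.to_numpy().T).mean(axis=1), 0.0, 1.0),
        index=probes,
        name="baseline_beta",
    )
    truth = SimulationTruth(
        true_cell_proportions=proportions,
        true_latent_age_signal=latent,
        baseline_beta=baseline,
        fluctuation_sd=sds,
        ar1_coefficient=phi,
        probe_noise_sd=probe_noise,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# annotations and phenotypes


def generate_annotations(
    probe_ids,
    category_probs: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign each probe one category per annotation axis.

    Axes and their default category frequencies approximate a 450k-style
    array (design type I/II, CpG-island relation, genic category).
    """
    probs = {k: dict(v) for k, v in DEFAULT_CATEGORY_PROBS.items()}
    if category_probs:
        for axis, dist in category_probs.items():
            if axis not in probs:
                raise InvalidArgumentError(f"unknown annotation axis {axis!r}")
            probs[axis] = dict(dist)
    for axis, dist in probs.items():
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidArgumentError(
                f"category probabilities for {axis!r} sum to {total}, expected 1"
            )
    probe_ids = list(probe_ids)
    rng = np.random.default_rng(seed)
    out = {"probe_id": probe_ids}
    for axis, dist in probs.items():
        cats = list(dist)
        p = np.array([dist[c] for c in cats], dtype=float)
        p = p / p.sum()
        out[axis] = rng.choice(cats, size=len(probe_ids), p=p) if probe_ids else []
    return pd.DataFrame(out, columns=["probe_id", *probs])


DEFAULT_PHENOTYPE_ITEMS = ("gamma_gtp", "ast", "alt", "glucose", "crp")


def generate_phenotypes(
    design: StudyDesign,
    linked_signal: pd.Series | np.ndarray | None = None,
    effect: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    items=DEFAULT_PHENOTYPE_ITEMS,
    linked_item: str | None = None,
) -> pd.DataFrame:
    """Blood-test-like phenotype values, one row per sample.

    The designated ``linked_item`` (default: the first item) equals
    ``effect × linked_signal + N(0, noise_sd)``; every other item is pure
    standard-normal noise, independent of the signal.
    """
    sheet = design.sample_sheet()
    n = len(sheet)
    if linked_signal is not None:
        signal = np.asarray(
            linked_signal.to_numpy() if isinstance(linked_signal, pd.Series) else linked_signal,
            dtype=float,
        )
        if signal.shape != (n,):
            raise InvalidArgumentError(
                f"linked_signal has length {signal.shape[0]}, expected {n} samples"
            )
    else:
        signal = np.zeros(n)
    rng = np.random.default_rng(seed)
    linked_item = linked_item or items[0]
    if linked_item not in items:
        raise InvalidArgumentError(f"linked_item {linked_item!r} not among items")
    data = {"sample_id": sheet["sample_id"]}
    for item in items:
        if item == linked_item:
            data[item] = effect * signal + rng.normal(0.0, noise_sd, size=n)
        else:
            data[item] = rng.standard_normal(n)
    return pd.DataFrame(data)
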