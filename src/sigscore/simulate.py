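"""Synthetic cohort generation for the scoring and survival pipeline.

The generator emulates the structure the retrospective analysis relies on:
healthy subjects are predominantly eubiotic (mostly SIG2+, very few
SIG1+), cancer patients are predominantly dysbiotic or gray; *Akkermansia
muciniphila* follows a trichotomy (absent / normal / overabundant above
4.799%); and overall survival shortens with the number of detected SIG1
taxa through a proportional-hazards model.

Because catalog taxa are detected independently given a sample's
prevalences, a single group-level prevalence cannot spread SIG scores
across all three label categories (the binomial score spread is ~0.05
while the label bands span ~0.26). Each sample therefore draws a latent
community state — eubiotic, intermediate, or dysbiotic — whose per-state
SIG prevalences pin the score firmly inside one label band, so the state
mixture weights are, by construction, the generator's label-mixture
calibration targets. Defaults follow the published cohort label fractions
(healthy ~68% SIG2 / ~4% SIG1, cancer 34% SIG1 / ~23% SIG2) and sizes
(5346 healthy, 955 cancer). Explicit per-group prevalence overrides bypass
the state mixture entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import SigCatalog, default_catalog, normalize_taxon_name
from .cohort import CohortRecord
from .errors import ValidationError
from .ingest import AbundanceTable, table_from_arrays

STATE_EUBIOTIC = "eubiotic"
STATE_INTERMEDIATE = "intermediate"
STATE_DYSBIOTIC = "dysbiotic"
STATES = (STATE_DYSBIOTIC, STATE_INTERMEDIATE, STATE_EUBIOTIC)

AKK_ABSENT = "absent"
AKK_NORMAL = "normal"
AKK_OVER = "over"

#: per-state (SIG1 prevalence, SIG2 prevalence); chosen so each state maps
#: to its primary label with > 98% probability under the 37/45 catalog
STATE_PREVALENCES: dict[str, tuple[float, float]] = {
    STATE_EUBIOTIC: (0.05, 0.85),
    STATE_INTERMEDIATE: (0.30, 0.60),
    STATE_DYSBIOTIC: (0.50, 0.25),
}


def _as_mix(v) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValidationError("mixture must have three proportions")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator; fully determines a cohort given
    the seed.

    ``state_mix_*`` are the (dysbiotic, intermediate, eubiotic) weights —
    the label-mixture calibration targets. ``sig*_prevalence_*``, when set
    (scalar or per-taxon vector), replace the state mixture with one fixed
    prevalence per group. ``akk_mix_*`` are (absent, normal, over)
    proportions of the Akkermansia trichotomy. ``beta_sig1`` > 0 multiplies
    the death hazard by exp(beta_sig1) per detected SIG1 taxon, so a higher
    SIG1 burden means shorter survival.
    """

    seed: int = 0
    n_healthy: int = 5346
    n_cancer: int = 955
    state_mix_healthy: tuple[float, float, float] = (0.04, 0.28, 0.68)
    state_mix_cancer: tuple[float, float, float] = (0.34, 0.43, 0.23)
    sig1_prevalence_healthy: float | Sequence[float] | None = None
    sig2_prevalence_healthy: float | Sequence[float] | None = None
    sig1_prevalence_cancer: float | Sequence[float] | None = None
    sig2_prevalence_cancer: float | Sequence[float] | None = None
    akk_mix_healthy: tuple[float, float, float] = (0.25, 0.65, 0.10)
    akk_mix_cancer: tuple[float, float, float] = (0.45, 0.40, 0.15)
    log_abundance_mean: float = -2.0   # ln of percent for detected taxa
    log_abundance_sd: float = 1.5
    filler_taxa: int = 150
    filler_prevalence: float = 0.3
    akk_over_max: float = 15.0         # upper bound of the "over" stratum
    beta_sig1: float = 0.15            # log-hazard per detected SIG1 taxon
    baseline_hazard: float = 0.02      # events per month at zero SIG1 burden
    pfs_hazard_ratio: float = 2.0
    censor_rate: float = 0.1
    followup_max: float = 60.0         # months

    def validate(self, catalog: SigCatalog) -> "SimulationConfig":
        if self.n_healthy < 0 or self.n_cancer < 0:
            raise ValidationError("n_healthy and n_cancer must be >= 0")
        if self.followup_max <= 0:
            raise ValidationError("followup_max must be positive")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be positive")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValidationError("censor_rate must lie in [0, 1]")
        if self.filler_taxa < 0:
            raise ValidationError("filler_taxa must be >= 0")
        if self.akk_over_max <= 4.799:
            raise ValidationError(
                "akk_over_max must exceed the overabundance cutoff")
        for name in ("state_mix_healthy", "state_mix_cancer",
                     "akk_mix_healthy", "akk_mix_cancer"):
            mix = _as_mix(getattr(self, name))
            if any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
                raise ValidationError(
                    f"{name} must be non-negative and sum to 1, got {mix}")
        for name, size in (("sig1_prevalence_healthy", catalog.n_sig1),
                           ("sig2_prevalence_healthy", catalog.n_sig2),
                           ("sig1_prevalence_cancer", catalog.n_sig1),
                           ("sig2_prevalence_cancer", catalog.n_sig2)):
            v = getattr(self, name)
            if v is None:
                continue
            arr = np.atleast_1d(np.asarray(v, dtype=float))
            if arr.size not in (1, size):
                raise ValidationError(
                    f"{name} must be a scalar or length-{size} vector")
            if ((arr < 0) | (arr > 1)).any():
                raise ValidationError(f"{name} must lie in [0, 1]")
        return self


@dataclass(frozen=True)
class SimulatedCohort:
    """A generated cohort: abundance table, clinical records, and the
    generative truth per sample."""

    table: AbundanceTable
    clinical: list[CohortRecord]
    truth: pd.DataFrame
    config: SimulationConfig


def _prevalence_rows(config: SimulationConfig, group: str, states: np.ndarray,
                     n_taxa: int, which: str) -> np.ndarray:
    """Per-sample x per-taxon detection probabilities for one SIG group."""
    override = getattr(config, f"{which}_prevalence_{group}")
    n = len(states)
    if override is not None:
        arr = np.atleast_1d(np.asarray(override, dtype=float))
        row = np.full(n_taxa, arr[0]) if arr.size == 1 else arr
        return np.tile(row, (n, 1))
    idx = 0 if which == "sig1" else 1
    per_state = np.array([STATE_PREVALENCES[s][idx] for s in STATES])
    return np.tile(per_state[states][:, None], (1, n_taxa))


def simulate_cohort(config: SimulationConfig | None = None,
                    catalog: SigCatalog | None = None) -> SimulatedCohort:
    """Generate a reproducible synthetic cohort under ``config``.

    Every catalog taxon is detected independently with its per-sample
    probability; detected abundances are log-normal; Akkermansia is drawn
    from its trichotomy stratum (absent 0; normal uniform in (0, 4.799];
    over uniform in (4.799, akk_over_max]); filler taxa pad the table; and
    overall/progression-free survival times are exponential with hazard
    baseline_hazard * exp(beta_sig1 * n_detected_SIG1), administratively
    censored at followup_max and randomly at censor_rate.
    """
    config = config or SimulationConfig()
    catalog = catalog or default_catalog()
    config.validate(catalog)
    rng = np.random.default_rng(config.seed)
    cutoff = catalog.akk_over_cutoff

    sig1_taxa = list(catalog.sig1)
    sig2_taxa = list(catalog.sig2)
    filler = [normalize_taxon_name(f"Filler taxon {i + 1:03d}")
              for i in range(config.filler_taxa)]
    taxa = sig1_taxa + sig2_taxa + [catalog.akkermansia] + filler

    all_values = []
    truth_rows = []
    clinical: list[CohortRecord] = []
    sample_ids: list[str] = []

    for group, n, prefix in (("healthy", config.n_healthy, "H"),
                             ("cancer", config.n_cancer, "C")):
        if n == 0:
            continue
        state_mix = _as_mix(getattr(config, f"state_mix_{group}"))
        akk_mix = _as_mix(getattr(config, f"akk_mix_{group}"))
        states = rng.choice(len(STATES), size=n, p=state_mix)

        p1 = _prevalence_rows(config, group, states, len(sig1_taxa), "sig1")
        p2 = _prevalence_rows(config, group, states, len(sig2_taxa), "sig2")
        det1 = rng.random((n, len(sig1_taxa))) < p1
        det2 = rng.random((n, len(sig2_taxa))) < p2
        detf = rng.random((n, len(filler))) < config.filler_prevalence

        def _abundances(mask: np.ndarray) -> np.ndarray:
            ab = np.zeros(mask.shape)
            k = int(mask.sum())
            if k:
                ab[mask] = np.exp(rng.normal(config.log_abundance_mean,
                                             config.log_abundance_sd, size=k))
            return ab

        ab1, ab2, abf = _abundances(det1), _abundances(det2), _abundances(detf)
        strata = rng.choice(3, size=n, p=akk_mix)  # 0 absent, 1 normal, 2 over
        akk = np.zeros(n)
        normal = strata == 1
        over = strata == 2
        akk[normal] = rng.uniform(1e-6, cutoff, size=int(normal.sum()))
        akk[over] = rng.uniform(np.nextafter(cutoff, np.inf),
                                config.akk_over_max, size=int(over.sum()))

        values = np.hstack([ab1, ab2, akk[:, None], abf])
        # keep compositional validity; scale non-Akkermansia mass if a row
        # overflows so the trichotomy stratum is preserved
        akk_col = len(sig1_taxa) + len(sig2_taxa)
        totals = values.sum(axis=1)
        overflow = totals > 99.0
        if overflow.any():
            other = totals[overflow] - values[overflow, akk_col]
            budget = 99.0 - values[overflow, akk_col]
            scale = np.where(other > 0, budget / other, 1.0)
            values[overflow] *= scale[:, None]
            values[overflow, akk_col] = akk[overflow]

        n_sig1 = det1.sum(axis=1)
        n_sig2 = det2.sum(axis=1)
        hazard = config.baseline_hazard * np.exp(config.beta_sig1 * n_sig1)
        t_os = rng.exponential(1.0 / hazard)
        t_pfs = np.minimum(
            rng.exponential(1.0 / (hazard * config.pfs_hazard_ratio)), t_os)
        censored = rng.random(n) < config.censor_rate
        c_rand = np.where(censored, rng.uniform(0, config.followup_max, n),
                          np.inf)
        c_time = np.minimum(c_rand, config.followup_max)
        os_months = np.minimum(t_os, c_time)
        os_event = t_os <= c_time
        pfs_months = np.minimum(t_pfs, c_time)
        pfs_event = t_pfs <= c_time

        ids = [f"{prefix}{i + 1:05d}" for i in range(n)]
        sample_ids.extend(ids)
        all_values.append(values)
        for i, sid in enumerate(ids):
            clinical.append(CohortRecord(
                sample_id=sid, group=group,
                cancer_type="other" if group == "cancer" else None,
                os_months=float(os_months[i]), os_event=bool(os_event[i]),
                pfs_months=float(pfs_months[i]),
                pfs_event=bool(pfs_event[i])))
            truth_rows.append({
                "sample_id": sid, "group": group,
                "state": STATES[states[i]],
                "n_sig1_true": int(n_sig1[i]), "n_sig2_true": int(n_sig2[i]),
                "akk_stratum": (AKK_ABSENT, AKK_NORMAL, AKK_OVER)[strata[i]],
                "akk_abundance": float(akk[i]),
                "hazard": float(hazard[i]),
                "detected_sig1": ";".join(
                    t.canonical for t, d in zip(sig1_taxa, det1[i]) if d),
                "detected_sig2": ";".join(
                    t.canonical for t, d in zip(sig2_taxa, det2[i]) if d),
            })

    if not all_values:
        raise ValidationError("cohort is empty (n_healthy = n_cancer = 0)")
    table = table_from_arrays(sample_ids, taxa, np.vstack(all_values))
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(table=table, clinical=clinical, truth=truth,
                           config=config)


def planted_block_table(n_samples: int,
                        blocks: Sequence[tuple[int, float]],
                        between_rho: float = 0.0,
                        seed: int = 0) -> AbundanceTable:
    """Abundance table with a planted block-correlation structure.

    Draws a Gaussian copula with within-block correlation per block and
    ``between_rho`` across blocks, mapped through a log-normal to relative
    abundances and closed to a constant per-sample total. Raises when the
    target correlation matrix is not positive semi-definite.
    """
    if not blocks:
        raise ValidationError("need at least one block")
    for size, rho in blocks:
        if size < 1:
            raise ValidationError("block sizes must be >= 1")
        if abs(rho) > 1:
            raise ValidationError("within-block correlation must be in [-1, 1]")
    if abs(between_rho) > 1:
        raise ValidationError("between_rho must be in [-1, 1]")

    sizes = [size for size, _ in blocks]
    p = sum(sizes)
    corr = np.full((p, p), float(between_rho))
    start = 0
    for size, rho in blocks:
        corr[start:start + size, start:start + size] = rho
        start += size
    np.fill_diagonal(corr, 1.0)
    eig_min = np.linalg.eigvalsh(corr).min()
    if eig_min < -1e-8:
        raise ValidationError(
            f"target correlation matrix is not PSD (min eigenvalue {eig_min:.3g})")

    rng = np.random.default_rng(seed)
    jitter = max(0.0, -eig_min) + 1e-10
    chol = np.linalg.cholesky(corr + jitter * np.eye(p))
    z = rng.standard_normal((n_samples, p)) @ chol.T
    values = np.exp(-2.0 + 1.0 * z)
    # the per-taxon monotone map preserves rank correlations exactly; only
    # rescale the rare overflowing rows to keep the table compositional
    totals = values.sum(axis=1)
    overflow = totals > 99.0
    if overflow.any():
        values[overflow] *= (99.0 / totals[overflow])[:, None]

    taxa = []
    for b, (size, _) in enumerate(blocks):
        for j in range(size):
            taxa.append(normalize_taxon_name(
                f"Block{b + 1:02d} taxon {j + 1:03d}"))
    return table_from_arrays(
        [f"S{i + 1:05d}" for i in range(n_samples)], taxa, values)
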