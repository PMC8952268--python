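"""Synthetic two-reactor chain-elongation experiments with planted bioindicators.

The generator emulates the statistical structure of a 211-day, two-bioreactor
hydraulic-retention-time (HRT) ramp experiment: reactor A steps its HRT down
gradually (8 -> 6 -> 4 -> 2 d at days 51/101/141) while reactor B stays at
8 d and then switches directly to 2 d at day 141.  Each reactor is sampled at
59 time points.  ASV abundances are log-normal latent series with AR(1)
temporal autocorrelation, closed to compositions and observed through
multinomial read sampling at a fixed depth.  A planted subset of ASVs
("responders") shifts its latent baseline when the HRT drops, with a logistic
transition over about a week to mimic community adaptation.  Most responders
("coupled") co-bloom with a shared elongation-guild activity factor that
drives the process parameters; a small "time-independent" subset responds to
HRT but is decoupled from the guild.  Two further groups provide the
confounders the non-HRT-bioindicator logic must separate out: pure
time-trend drifters (monotone in day, uncoupled from performance) and guild
satellites (track the guild's wobble without responding to HRT or causing
production).  Process parameters (C4/C6/C8 productivities, concentrations
and yields, residual lactate) are noisy linear functions of the coupled
responders' relative abundances, with concentrations tied to productivities
through the HRT (concentration = productivity x HRT).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (
    AbundanceTable,
    SampleMetadata,
    TaxonomyTable,
    METADATA_COLUMNS,
    write_abundance_table,
    write_metadata,
    write_taxonomy_table,
)

#: per-interval sampling counts per reactor: 7 + 16 + 16 + 20 = 59 points,
#: reproducing the 14 (HRT8) vs 40 (HRT2) labeled-sample split across the
#: two reactors.
SAMPLES_PER_INTERVAL: tuple[int, ...] = (7, 16, 16, 20)

_GENERA = (
    "Olsenella", "Lactobacillus", "Syntrophococcus", "Clostridium IV",
    "Caproiciproducens", "Pseudoramibacter", "Megasphaera", "Prevotella",
    "Bifidobacterium", "Eubacterium", "Acinetobacter", "Bacteroides",
)


def hrt_at(reactor: str, day: float) -> float:
    """Scheduled HRT (d) of a reactor at a given day."""
    if reactor == "A":
        if day <= 50:
            return 8.0
        if day <= 100:
            return 6.0
        if day <= 140:
            return 4.0
        return 2.0
    if reactor == "B":
        return 8.0 if day <= 140 else 2.0
    raise ValueError(f"unknown reactor {reactor!r}")


def sampling_days() -> np.ndarray:
    """The 59 sampling days per reactor (twice-weekly-like grid, 0-211 d)."""
    days: list[int] = []
    bounds = ((0, 50), (51, 100), (101, 140), (141, 211))
    for (lo, hi), n in zip(bounds, SAMPLES_PER_INTERVAL):
        days.extend(np.round(np.linspace(lo, hi, n)).astype(int))
    return np.asarray(days)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; defaults mirror the study layout."""

    n_asvs: int = 71
    n_responders: int = 11
    overlap_time_independent: int = 4  # responders NOT coupled to performance
    n_drift: int = 14                  # non-responders drifting with time
    n_satellites: int = 0              # optional guild-tracking non-responders
    effect_size: float = 2.0           # log-units abundance shift HRT8 -> HRT2
    ar1_rho: float = 0.6
    noise_sd: float = 0.5              # latent log-abundance innovation sd
    transition_days: float = 7.0       # logistic adaptation width
    read_depth: int = 13518
    process_noise_sd: float = 1.5      # mmol C L^-1 d^-1 on productivities
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders + self.n_drift + self.n_satellites > self.n_asvs:
            raise ValueError("planted groups cannot exceed n_asvs")
        if self.overlap_time_independent > self.n_responders:
            raise ValueError("time-independent subset larger than responder set")
        if not (0 <= self.ar1_rho < 1):
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")


@dataclass
class GroundTruth:
    """What was planted: responder ids, the time-independent subset, couplings."""

    responder_asv_ids: list[str]
    time_independent_ids: list[str]
    drift_asv_ids: list[str]
    satellite_asv_ids: list[str] = field(default_factory=list)
    coupling_c6: dict[str, float] = field(default_factory=dict)
    coupling_c8: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _latent_series(rng, n_time, baseline, shift_path, rho, noise_sd):
    """AR(1) log-abundance series around baseline + time-varying shift."""
    z = np.zeros(n_time)
    z[0] = rng.normal(0.0, noise_sd)
    innov_sd = noise_sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n_time):
        z[t] = rho * z[t - 1] + rng.normal(0.0, innov_sd)
    return baseline + shift_path + z


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[AbundanceTable, SampleMetadata, GroundTruth]:
    """Generate counts, metadata and ground truth for a two-reactor run.

    Returns 2 x 59 = 118 samples whose rows each sum to ``config.read_depth``.
    """
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(4)
    rng_setup = np.random.default_rng(streams[0])   # baselines, couplings, roles
    rng_abund = np.random.default_rng(streams[1])   # AR(1) innovations
    rng_reads = np.random.default_rng(streams[2])   # multinomial read noise
    rng_noise = np.random.default_rng(streams[3])   # process-parameter noise

    p = config.n_asvs
    asv_ids = [f"ASV{i + 1:03d}" for i in range(p)]

    responders = list(range(config.n_responders))
    time_independent = responders[: config.overlap_time_independent]
    coupled_responders = responders[config.overlap_time_independent:]
    drift = list(range(config.n_responders, config.n_responders + config.n_drift))
    satellites = list(range(drift[-1] + 1 if drift else config.n_responders,
                            (drift[-1] + 1 if drift else config.n_responders)
                            + config.n_satellites))

    # latent log-abundance baselines; responders, drift ASVs and guild
    # satellites start as modest community members (their fold-change carries
    # the signal, and a small starting share keeps the compositional closure
    # echo on the rest of the community weak)
    baseline = rng_setup.normal(0.0, 1.2, size=p)
    baseline[responders] = rng_setup.normal(-0.9, 0.4, size=len(responders))
    baseline[drift] = rng_setup.normal(-0.4, 0.4, size=len(drift))
    baseline[satellites] = rng_setup.normal(-0.4, 0.4, size=len(satellites))

    # responders shift when HRT drops; most up-shift (chain elongators favored
    # at short HRT), a minority down-shift
    signs = np.ones(config.n_responders)
    n_down = max(1, config.n_responders // 4) if config.n_responders >= 4 else 0
    if n_down:
        down = rng_setup.choice(config.n_responders, size=n_down, replace=False)
        signs[down] = -1.0
        # decliners start abundant (like C4-stage fermenters outcompeted at
        # short HRT) so their decrease stays quantifiable after sequencing
        baseline[np.asarray(responders)[down]] += config.effect_size

    # performance couples linearly to the elongation guild: the coupled
    # responders, the time-driven drift bloomers (with a heavier weight:
    # their slow blooms carry the within-phase productivity trend) and,
    # when present, guild satellites at half weight
    coupled = coupled_responders + drift + satellites
    guild_load = {
        i: float(rng_setup.uniform(0.8, 1.2))
        for i in coupled_responders + drift + satellites
    }
    # couplings scaled inversely to baseline abundance so every guild member
    # contributes a comparable share of the productivity variance, then
    # normalized so the deterministic HRT-8 baseline productivity is fixed
    # across realizations (C6 ~ 12, C8 ~ 1.5 mmol C L^-1 d^-1)
    rel_scale = {i: float(np.exp(baseline[i])) for i in coupled}
    mean_scale = float(np.mean(list(rel_scale.values())))
    beta_c6 = {
        asv_ids[i]: float(rng_setup.uniform(0.8, 1.2))
        * (0.5 if i in satellites else (0.4 if i in drift else 1.0))
        * mean_scale / rel_scale[i]
        for i in coupled
    }
    beta_c8 = {
        asv_ids[i]: float(rng_setup.uniform(0.8, 1.2))
        * (0.5 if i in satellites else (0.4 if i in drift else 1.0))
        * mean_scale / rel_scale[i]
        for i in coupled
    }
    comp0 = np.exp(baseline)
    comp0 /= comp0.sum()
    agg0 = float(sum(beta_c6[asv_ids[i]] * comp0[i] for i in coupled))
    for i in coupled:
        beta_c6[asv_ids[i]] *= 12.0 / agg0
    agg0_c8 = float(sum(beta_c8[asv_ids[i]] * comp0[i] for i in coupled))
    for i in coupled:
        beta_c8[asv_ids[i]] *= 1.5 / agg0_c8

    days = sampling_days()
    n_time = len(days)

    rows, meta_rows = [], []
    for reactor in ("A", "B"):
        hrt = np.array([hrt_at(reactor, d) for d in days])
        # HRT-driven modulation in [0, 1]: 0 at 8 d, 1 at 2 d, smoothed by a
        # logistic adaptation lag of ~transition_days after each step change
        raw = (8.0 - hrt) / 6.0
        smooth = np.empty(n_time)
        state = raw[0]
        for t in range(n_time):
            dt = days[t] - days[t - 1] if t else 0.0
            # first-order relaxation toward the scheduled level
            tau = max(config.transition_days / 2.0, 1e-6)
            state = raw[t] + (state - raw[t]) * np.exp(-dt / tau)
            smooth[t] = state

        # the HRT-responsive elongation guild co-blooms around the HRT-driven
        # trajectory: coupled responders and their satellites share one
        # activity factor, so any member tracks the guild (and hence
        # productivity); the time-independent responders shift with HRT but
        # carry only spiky idiosyncratic noise, and the drift group is a pure
        # time trend uncoupled from performance
        guild = _latent_series(
            rng_abund, n_time, 0.0, np.zeros(n_time), config.ar1_rho,
            0.7 * config.noise_sd,
        )
        guild -= guild.mean()  # stationary wobble around the HRT trajectory
        latents = np.empty((n_time, p))
        for j in range(p):
            shift = np.zeros(n_time)
            idio_sd = config.noise_sd
            if j in responders:
                shift = signs[responders.index(j)] * config.effect_size * smooth
                if j in coupled_responders:
                    shift = shift + guild_load[j] * guild
                    idio_sd = 0.1 * config.noise_sd
                else:
                    # time-independent responders: clean HRT markers but
                    # noisy, spiky ones (transient blooms), decoupled from
                    # the guild's activity swings
                    idio_sd = 0.85 * config.noise_sd
            elif j in drift:
                # monotone bloom over the run, independent of HRT, riding
                # the same guild activity as the coupled responders
                shift = 1.0 * days / days[-1] + 1.1 * guild
                idio_sd = 0.1 * config.noise_sd
            elif j in satellites:
                shift = guild_load[j] * guild
                idio_sd = 0.1 * config.noise_sd
            rho_j = 0.2 if j in time_independent else config.ar1_rho
            latents[:, j] = _latent_series(
                rng_abund, n_time, baseline[j], shift, rho_j, idio_sd
            )

        comp = np.exp(latents)
        comp /= comp.sum(axis=1, keepdims=True)

        counts = np.vstack([
            rng_reads.multinomial(config.read_depth, comp[t]) for t in range(n_time)
        ])

        # process performance from latent (pre-sequencing) relative abundances
        prod_c6 = 3.0 + comp @ np.array([beta_c6.get(a, 0.0) for a in asv_ids])
        prod_c8 = 0.3 + comp @ np.array([beta_c8.get(a, 0.0) for a in asv_ids])
        prod_c6 = np.clip(prod_c6 + rng_noise.normal(0, config.process_noise_sd, n_time), 0, None)
        prod_c8 = np.clip(prod_c8 + rng_noise.normal(0, config.process_noise_sd / 4, n_time), 0, None)
        # n-butyrate: high throughout, mildly suppressed when elongators bloom
        prod_c4 = np.clip(
            70.0 - 0.3 * prod_c6 + rng_noise.normal(0, 2.0, n_time), 0, None
        )
        conc_c4, conc_c6, conc_c8 = prod_c4 * hrt, prod_c6 * hrt, prod_c8 * hrt
        # residual lactate: consumed faster when elongation is active
        conc_lactate = np.clip(
            60.0 - 0.5 * prod_c6 + rng_noise.normal(0, 4.0, n_time), 0, None
        )
        total_prod = prod_c4 + prod_c6 + prod_c8 + 1e-9
        yields = {}
        for name, prod in (("C4", prod_c4), ("C6", prod_c6), ("C8", prod_c8)):
            y = 0.85 * prod / total_prod + rng_noise.normal(0, 0.01, n_time)
            yields[name] = np.clip(y, 0.0, None)

        for t in range(n_time):
            sid = f"{reactor}{t + 1:02d}"
            rows.append((sid, counts[t]))
            meta_rows.append({
                "sample_id": sid, "reactor": reactor,
                "day": int(days[t]), "hrt": float(hrt[t]),
                "conc_lactate": conc_lactate[t],
                "conc_C4": conc_c4[t], "conc_C6": conc_c6[t], "conc_C8": conc_c8[t],
                "prod_C4": prod_c4[t], "prod_C6": prod_c6[t], "prod_C8": prod_c8[t],
                "yield_C4": yields["C4"][t], "yield_C6": yields["C6"][t],
                "yield_C8": yields["C8"][t],
            })

    table = AbundanceTable(
        pd.DataFrame(
            np.vstack([r[1] for r in rows]).astype(np.int64),
            index=[r[0] for r in rows],
            columns=asv_ids,
        ),
        "counts",
    )
    meta = SampleMetadata(pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS)))
    truth = GroundTruth(
        responder_asv_ids=[asv_ids[i] for i in responders],
        time_independent_ids=[asv_ids[i] for i in time_independent],
        drift_asv_ids=[asv_ids[i] for i in drift],
        satellite_asv_ids=[asv_ids[i] for i in satellites],
        coupling_c6=beta_c6,
        coupling_c8=beta_c8,
    )
    return table, meta, truth


def synthetic_taxonomy(asv_ids: list[str], seed: int = 0) -> TaxonomyTable:
    """Plausible genus labels for synthetic ASVs (round-robin over CE taxa)."""
    rows = []
    for i, asv in enumerate(asv_ids):
        genus = _GENERA[i % len(_GENERA)]
        rows.append({
            "asv_id": asv, "phylum": "Firmicutes", "class": "Clostridia",
            "order": "Clostridiales", "family": "unclassified", "genus": genus,
        })
    return TaxonomyTable(pd.DataFrame(rows).set_index("asv_id"))


def write_fixture(
    bundle: tuple[AbundanceTable, SampleMetadata, GroundTruth],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write abundance/metadata/taxonomy TSVs plus a ground-truth JSON sidecar."""
    table, meta, truth = bundle
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": out / "abundance.tsv",
        "metadata": out / "metadata.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_abundance_table(table, paths["abundance"])
    write_metadata(meta, paths["metadata"])
    write_taxonomy_table(synthetic_taxonomy(table.asv_ids), paths["taxonomy"])
    paths["ground_truth"].write_text(truth.to_json() + "\n")
    return paths
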