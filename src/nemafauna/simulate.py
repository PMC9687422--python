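"""Synthetic warming-gradient nematode community generator.

The study system is an alpine-meadow open-top-chamber warming experiment:
5 treatments (CK = control, A-D = increasing warming) x 3 replicate plots x
5 depth layers (0-5, 5-10, 10-20, 20-30, 30-40 cm).  No raw field counts are
distributed with the study, so this module generates datasets with the same
design and the published summary structure, for testing every downstream
stage end-to-end:

* per-sample expected total count = surface density x layer weight x
  dry mass / 100, realized as a negative-binomial draw (field nematode
  counts are overdispersed relative to Poisson);
* genus counts drawn from a two-stage guild-then-genus multinomial, so the
  per-treatment trophic proportions (Ba/Fu/Pp/Op) are directly controllable
  -- the defaults use the published per-treatment relative abundances;
* soil water content drawn around treatment means declining linearly from
  61.27% (CK) to 29.13% (D), the published endpoints;
* fresh soil mass uniform on 50-70 g, the weighing range of the protocol.

Identical seeds give bit-identical matrices across processes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .community import CommunityMatrix, CommunitySample, DEPTH_LAYERS, TREATMENTS
from .errors import ConfigError, DesignError
from .taxonomy import GUILDS, TaxonomyTable, default_taxonomy

#: per-treatment guild composition (fractions of individuals).  Ba for all
#: five treatments, Fu for CK/B/D and Pp for CK/B/D follow the published
#: values; Fu for A and C are interpolated and Op is the residual.
DEFAULT_TROPHIC = {
    "CK": {"Ba": 0.4031, "Fu": 0.1342, "Pp": 0.2872, "Op": 0.1755},
    "A":  {"Ba": 0.3131, "Fu": 0.1150, "Pp": 0.3500, "Op": 0.2219},
    "B":  {"Ba": 0.3380, "Fu": 0.0762, "Pp": 0.4317, "Op": 0.1541},
    "C":  {"Ba": 0.3800, "Fu": 0.1200, "Pp": 0.3200, "Op": 0.1800},
    "D":  {"Ba": 0.4714, "Fu": 0.1491, "Pp": 0.1410, "Op": 0.2385},
}

#: per-treatment mean gravimetric water content (wet basis), linear between
#: the published endpoints 61.27% (CK) and 29.13% (D).
DEFAULT_WATER = {"CK": 0.6127, "A": 0.5324, "B": 0.4520, "C": 0.3717, "D": 0.2913}

#: relative expected density by depth layer (surface = 1): nematodes
#: aggregate in the 0-5 cm topsoil and decline with depth.
DEFAULT_LAYER_WEIGHTS = {
    "0-5": 1.0, "5-10": 0.55, "10-20": 0.30, "20-30": 0.20, "30-40": 0.12,
}

#: within-guild genus weights; the dominant field genera get higher mass.
_DOMINANT = {"Acrobeloides", "Acrobeles", "Cervidellus", "Rotylenchus",
             "Aphelenchus", "Labronemella", "Eudorylaimus"}


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults emulate the field design."""

    treatments: tuple = TREATMENTS
    n_replicates: int = 3
    depth_layers: dict = field(default_factory=lambda: dict(DEFAULT_LAYER_WEIGHTS))
    trophic: dict = field(default_factory=lambda: {
        t: dict(v) for t, v in DEFAULT_TROPHIC.items()
    })
    water_content: dict = field(default_factory=lambda: dict(DEFAULT_WATER))
    water_sd: float = 0.03
    surface_density: float = 420.0      # ind per 100 g dry soil at 0-5 cm
    fresh_mass_range: tuple = (50.0, 70.0)
    dispersion: float = 10.0            # NB size parameter; larger = closer to Poisson
    rng_seed: int = 42

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not self.depth_layers:
            raise ConfigError("at least one depth layer required")
        if any(w <= 0 for w in self.depth_layers.values()):
            raise ConfigError("depth layer weights must be positive")
        lo, hi = self.fresh_mass_range
        if not (0 < lo <= hi):
            raise ConfigError("fresh_mass_range must be a positive interval")
        if self.surface_density <= 0:
            raise ConfigError("surface_density must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        for t in self.treatments:
            props = self.trophic.get(t)
            if props is None:
                raise ConfigError(f"no trophic proportions for treatment {t!r}")
            if set(props) - set(GUILDS):
                raise ConfigError(f"treatment {t!r}: unknown guild in proportions")
            if any(p < 0 for p in props.values()):
                raise ConfigError(f"treatment {t!r}: negative trophic proportion")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ConfigError(
                    f"treatment {t!r}: trophic proportions sum to "
                    f"{sum(props.values()):.6f}, expected 1"
                )
            w = self.water_content.get(t)
            if w is None or not (0 <= w < 1):
                raise ConfigError(f"treatment {t!r}: water_content must be in [0, 1)")

    # ---- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["treatments"] = list(self.treatments)
        d["fresh_mass_range"] = list(self.fresh_mass_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "treatments" in d:
            d["treatments"] = tuple(d["treatments"])
        if "fresh_mass_range" in d:
            d["fresh_mass_range"] = tuple(d["fresh_mass_range"])
        try:
            cfg = cls(**d)
        except TypeError as exc:
            raise ConfigError(f"bad config field: {exc}") from None
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            if path.suffix.lower() == ".json":
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _genus_pool(taxonomy: TaxonomyTable) -> dict[str, tuple[list[str], np.ndarray]]:
    """guild -> (genus names, normalized within-guild frequencies)."""
    pool: dict[str, tuple[list[str], np.ndarray]] = {}
    for guild in GUILDS:
        names = sorted(
            e.genus_name for e in taxonomy.entries() if e.guild == guild
        )
        if not names:
            continue
        weights = np.array(
            [4.0 if n in _DOMINANT else 1.0 for n in names], dtype=float
        )
        pool[guild] = (names, weights / weights.sum())
    return pool


def generate_dataset(config: SimConfig | None = None,
                     taxonomy: TaxonomyTable | None = None,
                     seed: int | None = None) -> CommunityMatrix:
    """Generate one full study-shaped dataset.

    One sample per (treatment, replicate, layer).  ``seed`` overrides
    ``config.rng_seed``.  Identical config + seed gives identical output.
    """
    config = config or SimConfig()
    config.validate()
    taxonomy = taxonomy or default_taxonomy()
    pool = _genus_pool(taxonomy)
    missing = [g for g in GUILDS if g not in pool]
    if missing:
        raise ConfigError(
            "taxonomy has no genera for guild(s): " + ", ".join(missing)
        )
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    lo, hi = config.fresh_mass_range

    samples = []
    for treatment in config.treatments:
        props = config.trophic[treatment]
        guild_order = [g for g in GUILDS if props.get(g, 0.0) > 0]
        genus_names, genus_probs = [], []
        for g in guild_order:
            names, freqs = pool[g]
            genus_names.extend(names)
            genus_probs.extend(props[g] * freqs)
        genus_probs = np.asarray(genus_probs)
        genus_probs = genus_probs / genus_probs.sum()

        for rep in range(1, config.n_replicates + 1):
            for li, (layer, weight) in enumerate(config.depth_layers.items()):
                fresh = rng.uniform(lo, hi)
                water = float(np.clip(
                    rng.normal(config.water_content[treatment], config.water_sd),
                    0.01, 0.95,
                ))
                dry = fresh * (1.0 - water)
                mu = config.surface_density * weight * dry / 100.0
                k = config.dispersion
                total = int(rng.negative_binomial(k, k / (k + mu))) if mu > 0 else 0
                counts_vec = rng.multinomial(total, genus_probs)
                counts = {
                    name: int(c)
                    for name, c in zip(genus_names, counts_vec) if c > 0
                }
                samples.append(CommunitySample(
                    sample_id=f"{treatment}-R{rep}-L{li + 1}",
                    treatment=treatment,
                    depth_layer=layer,
                    replicate=rep,
                    fresh_mass=float(fresh),
                    water_content=water,
                    counts=counts,
                ))
    return CommunityMatrix(samples, taxonomy)


@dataclass
class RecoveredParameters:
    """Point estimates and standard errors recovered from a generated matrix."""

    layer_weights: dict        # layer -> normalized mean density (surface = 1)
    layer_weights_se: dict
    trophic: dict              # treatment -> guild -> fraction of individuals
    trophic_se: dict


def recover_parameters(matrix: CommunityMatrix) -> RecoveredParameters:
    """Estimate the depth-decay profile and per-treatment trophic fractions.

    Layer weights are mean per-sample densities (ind per 100 g dry soil)
    normalized by the shallowest layer; trophic fractions come from pooled
    counts per treatment with multinomial standard errors.
    """
    from .community import sample_density, tally_guild_cp

    if len(matrix) == 0:
        raise DesignError("empty matrix")
    layers = list(dict.fromkeys(s.depth_layer for s in matrix))
    dens: dict[str, list[float]] = {lay: [] for lay in layers}
    for s in matrix:
        dens[s.depth_layer].append(sample_density(s))
    means = {lay: float(np.mean(v)) for lay, v in dens.items()}
    ses = {
        lay: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        for lay, v in dens.items()
    }
    ref = means[layers[0]]
    if ref <= 0:
        raise DesignError("surface layer has zero mean density")
    layer_weights = {lay: means[lay] / ref for lay in layers}
    layer_weights_se = {lay: ses[lay] / ref for lay in layers}

    trophic: dict[str, dict[str, float]] = {}
    trophic_se: dict[str, dict[str, float]] = {}
    for treatment in dict.fromkeys(s.treatment for s in matrix):
        totals = {g: 0.0 for g in GUILDS}
        n = 0.0
        for s in matrix:
            if s.treatment != treatment:
                continue
            tally = tally_guild_cp(s, matrix.taxonomy, on_unresolved="carry")
            for g in GUILDS:
                totals[g] += tally.guild_total(g)
            n += tally.resolved_total
        if n <= 0:
            raise DesignError(f"treatment {treatment!r} has no individuals")
        fractions = {g: totals[g] / n for g in GUILDS}
        trophic[treatment] = fractions
        trophic_se[treatment] = {
            g: float(np.sqrt(f * (1 - f) / n)) for g, f in fractions.items()
        }
    return RecoveredParameters(layer_weights, layer_weights_se, trophic, trophic_se)
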