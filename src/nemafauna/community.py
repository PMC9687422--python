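"""Community data model, I/O, density standardization and aggregation.

A *sample* is one soil core section: genus counts plus the metadata needed to
standardize them (treatment label, depth layer, replicate, fresh soil mass,
gravimetric water content).  A *matrix* is the ordered collection of samples
making up a study design, bound to a taxonomy reference.  Counts are
standardized to individuals per 100 g dry soil before any density comparison.

Default water-content convention is wet-mass basis, w = (fresh - dry)/fresh,
so dry = fresh * (1 - w).  A dry-mass basis (w = (fresh - dry)/dry, so
dry = fresh / (1 + w)) is available via ``basis="dry"``; 105 degC oven drying
is compatible with either convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import LinkageError, UnknownTaxonError, ValidationError
from .errors import UndefinedIndexError
from .taxonomy import GUILDS, CP_VALUES, UNKNOWN_GUILD, TaxonomyTable, classify

TREATMENTS = ("CK", "A", "B", "C", "D")
DEPTH_LAYERS = ("0-5", "5-10", "10-20", "20-30", "30-40")

COUNTS_COLUMNS = ["sample_id", "genus", "count"]
META_COLUMNS = [
    "sample_id",
    "treatment",
    "depth_layer",
    "replicate",
    "fresh_mass_g",
    "water_content",
]


@dataclass
class CommunitySample:
    """Genus counts + metadata for one soil sample."""

    sample_id: str
    treatment: str
    depth_layer: str
    replicate: int
    fresh_mass: float
    water_content: float
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.fresh_mass <= 0:
            raise ValidationError(
                f"sample {self.sample_id}: fresh_mass must be > 0, got {self.fresh_mass}"
            )
        if not (0 <= self.water_content < 1):
            raise ValidationError(
                f"sample {self.sample_id}: water_content must be in [0, 1), "
                f"got {self.water_content}"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id}: replicate must be a positive integer"
            )
        for genus, n in self.counts.items():
            if n < 0 or int(n) != n:
                raise ValidationError(
                    f"sample {self.sample_id}: count for {genus!r} must be a "
                    f"non-negative integer, got {n}"
                )

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class CommunityMatrix:
    """Ordered collection of samples forming a study design."""

    samples: list[CommunitySample]
    taxonomy: TaxonomyTable
    unresolved_genera: set[str] = field(default_factory=set)

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample ids: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)


class GuildCpTally:
    """Per-sample abundances cross-classified by guild x c-p class.

    Cells may hold real (non-integer) abundances so that densities per
    100 g dry soil can be tallied with the same machinery as raw counts.
    Unresolved individuals are tracked separately: they contribute to
    :attr:`total` (they are real animals) but to no guild cell.
    """

    def __init__(self, cells: dict[tuple[str, int], float] | None = None,
                 unresolved: float = 0.0):
        self.cells: dict[tuple[str, int], float] = {}
        for (guild, cp), value in (cells or {}).items():
            if guild not in GUILDS:
                raise ValidationError(f"unknown guild {guild!r} in tally")
            if cp not in CP_VALUES:
                raise ValidationError(f"c-p value {cp!r} outside 1..5 in tally")
            if value < 0:
                raise ValidationError(f"negative abundance in cell ({guild}, {cp})")
            if value:
                self.cells[(guild, cp)] = self.cells.get((guild, cp), 0.0) + float(value)
        if unresolved < 0:
            raise ValidationError("negative unresolved abundance")
        self.unresolved = float(unresolved)

    def __getitem__(self, key: tuple[str, int]) -> float:
        return self.cells.get(key, 0.0)

    def guild_total(self, guild: str) -> float:
        return sum(v for (g, _), v in self.cells.items() if g == guild)

    @property
    def resolved_total(self) -> float:
        return sum(self.cells.values())

    @property
    def total(self) -> float:
        return self.resolved_total + self.unresolved

    def scaled(self, factor: float) -> "GuildCpTally":
        if factor < 0:
            raise ValidationError("scale factor must be non-negative")
        return GuildCpTally(
            {k: v * factor for k, v in self.cells.items()},
            unresolved=self.unresolved * factor,
        )


def density_per_100g_dry(count: float, fresh_mass: float, water_content: float,
                         basis: str = "wet") -> float:
    """Standardize an abundance to individuals per 100 g dry soil.

    ``basis="wet"`` (default): dry mass = fresh * (1 - w).
    ``basis="dry"``: dry mass = fresh / (1 + w).
    """
    if fresh_mass <= 0:
        raise ValidationError(f"fresh_mass must be > 0, got {fresh_mass}")
    if count < 0:
        raise ValidationError(f"count must be non-negative, got {count}")
    if basis == "wet":
        if not (0 <= water_content < 1):
            raise ValidationError(
                f"water_content must be in [0, 1) on wet basis, got {water_content}"
            )
        dry_mass = fresh_mass * (1.0 - water_content)
    elif basis == "dry":
        if water_content < 0:
            raise ValidationError(
                f"water_content must be >= 0 on dry basis, got {water_content}"
            )
        dry_mass = fresh_mass / (1.0 + water_content)
    else:
        raise ValidationError(f"basis must be 'wet' or 'dry', got {basis!r}")
    return count * 100.0 / dry_mass


def sample_density(sample: CommunitySample, basis: str = "wet") -> float:
    """Total individuals per 100 g dry soil for one sample."""
    return density_per_100g_dry(sample.total, sample.fresh_mass,
                                sample.water_content, basis=basis)


def tally_guild_cp(sample: CommunitySample, taxonomy: TaxonomyTable,
                   on_unresolved: str = "raise") -> GuildCpTally:
    """Cross-classify a sample's counts by guild x c-p class.

    ``on_unresolved="raise"`` (default) raises :class:`UnknownTaxonError` if
    any genus is missing from the taxonomy; ``"carry"`` keeps the individuals
    in the tally's ``unresolved`` bucket instead, so N is conserved.
    """
    if on_unresolved not in ("raise", "carry"):
        raise ValidationError(f"on_unresolved must be 'raise' or 'carry'")
    cells: dict[tuple[str, int], float] = {}
    unresolved = 0.0
    missing = []
    for genus, n in sample.counts.items():
        if n == 0:
            continue
        if genus in taxonomy:
            entry = classify(genus, taxonomy)
            key = (entry.guild, entry.cp_value)
            cells[key] = cells.get(key, 0.0) + n
        elif on_unresolved == "carry":
            unresolved += n
        else:
            missing.append(genus)
    if missing:
        raise UnknownTaxonError(missing)
    return GuildCpTally(cells, unresolved=unresolved)


def relative_abundance(tally: GuildCpTally) -> dict[str, float]:
    """Percent of resolved individuals in each guild; sums to 100."""
    denom = tally.resolved_total
    if denom <= 0:
        raise UndefinedIndexError(
            "relative_abundance", "no resolved individuals (N = 0)"
        )
    return {g: 100.0 * tally.guild_total(g) / denom for g in GUILDS}


def read_community(counts_path, meta_path, taxonomy: TaxonomyTable,
                   strict: bool = False) -> CommunityMatrix:
    """Assemble a CommunityMatrix from long-format counts + metadata CSVs.

    Unresolved genera are carried (flagged in ``matrix.unresolved_genera``)
    unless ``strict=True``, in which case they raise.
    """
    counts = pd.read_csv(counts_path, dtype={"sample_id": str, "genus": str})
    meta = pd.read_csv(meta_path, dtype={"sample_id": str})
    for col in COUNTS_COLUMNS:
        if col not in counts.columns:
            raise ValidationError(f"{counts_path}: missing column {col!r}")
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise ValidationError(f"{meta_path}: missing column {col!r}")
    if (counts["count"] < 0).any():
        bad = counts.loc[counts["count"] < 0].iloc[0]
        raise ValidationError(
            f"negative count for sample {bad['sample_id']}, genus {bad['genus']}"
        )
    meta_ids = set(meta["sample_id"])
    orphan = sorted(set(counts["sample_id"]) - meta_ids)
    if orphan:
        raise LinkageError(
            "samples in counts missing from metadata: " + ", ".join(orphan)
        )
    if meta["sample_id"].duplicated().any():
        raise ValidationError(f"{meta_path}: duplicate sample_id rows")

    grouped = {
        sid: dict(zip(grp["genus"], grp["count"].astype(int)))
        for sid, grp in counts.groupby("sample_id")
    }
    samples = []
    for row in meta.itertuples(index=False):
        samples.append(CommunitySample(
            sample_id=row.sample_id,
            treatment=str(row.treatment),
            depth_layer=str(row.depth_layer),
            replicate=int(row.replicate),
            fresh_mass=float(row.fresh_mass_g),
            water_content=float(row.water_content),
            counts=grouped.get(row.sample_id, {}),
        ))
    unresolved = {
        g for s in samples for g in s.counts if g not in taxonomy
    }
    if strict and unresolved:
        raise UnknownTaxonError(unresolved)
    return CommunityMatrix(samples, taxonomy, unresolved_genera=unresolved)


def write_community(matrix: CommunityMatrix, counts_path, meta_path) -> None:
    """Write a matrix to the long-format counts + metadata CSV pair."""
    count_rows = [
        {"sample_id": s.sample_id, "genus": g, "count": int(n)}
        for s in matrix
        for g, n in sorted(s.counts.items())
    ]
    pd.DataFrame(count_rows, columns=COUNTS_COLUMNS).to_csv(counts_path, index=False)
    meta_rows = [
        {
            "sample_id": s.sample_id,
            "treatment": s.treatment,
            "depth_layer": s.depth_layer,
            "replicate": s.replicate,
            "fresh_mass_g": s.fresh_mass,
            "water_content": s.water_content,
        }
        for s in matrix
    ]
    pd.DataFrame(meta_rows, columns=META_COLUMNS).to_csv(meta_path, index=False)


def to_wide(matrix: CommunityMatrix) -> pd.DataFrame:
    """Convenience wide-format view: samples x genera count table."""
    rows = {s.sample_id: s.counts for s in matrix}
    return (
        pd.DataFrame.from_dict(rows, orient="index")
        .fillna(0).astype(int).sort_index(axis=1)
    )


def pool_layers(matrix: CommunityMatrix, warn=None) -> CommunityMatrix:
    """Pool depth layers per (treatment, replicate) into 0-40 cm samples.

    Genus counts are summed layer-wise, fresh masses summed, and the pooled
    water content is the mass-weighted mean so that dry mass is conserved.
    A replicate missing one or more layers is pooled over the present layers
    and reported through ``warn`` (a callable receiving a message).
    """
    expected_layers = sorted({s.depth_layer for s in matrix})
    groups: dict[tuple[str, int], list[CommunitySample]] = {}
    for s in matrix:
        groups.setdefault((s.treatment, s.replicate), []).append(s)

    pooled = []
    for (treatment, rep), members in groups.items():
        present = sorted({m.depth_layer for m in members})
        if warn is not None and len(present) < len(expected_layers):
            missing = sorted(set(expected_layers) - set(present))
            warn(
                f"incomplete design: treatment {treatment} replicate {rep} "
                f"missing layers {', '.join(missing)}; pooling present layers"
            )
        counts: dict[str, int] = {}
        for m in members:
            for genus, n in m.counts.items():
                counts[genus] = counts.get(genus, 0) + int(n)
        fresh = sum(m.fresh_mass for m in members)
        # mass-weighted water content keeps total dry mass exact
        water = sum(m.fresh_mass * m.water_content for m in members) / fresh
        pooled.append(CommunitySample(
            sample_id=f"{treatment}-R{rep}-0-40",
            treatment=treatment,
            depth_layer="0-40",
            replicate=rep,
            fresh_mass=fresh,
            water_content=water,
            counts=counts,
        ))
    return CommunityMatrix(pooled, matrix.taxonomy,
                           unresolved_genera=set(matrix.unresolved_genera))
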