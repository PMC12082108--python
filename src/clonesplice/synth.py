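"""Synthetic dual-clone datasets with ground truth.

Emulates the statistical structure the downstream analyses assume:

* two mutant clones plus implicit WT competing under replicator dynamics,
  observed as ddPCR VAFs with binomial droplet noise;
* compartment-specific colony genotype draws with Poisson mutation accrual
  along clone trunks (clock-like: burden ~ rate x age);
* single-cell splice-junction counts with planted common and clone-biased
  PSI shifts, negative-binomial coverage, and junction geometry matching
  the declared event types.

All randomness flows from one seed: each generator draws from an
independent stream keyed as SeedSequence([seed, stream_id]) with fixed
stream ids (trajectories=1, colonies=2, junctions=3), so the three
generators are individually reproducible and mutually independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dynamics import VafTimeSeries
from .errors import InputError
from .model import replicator_fractions
from .phylo import BinaryMutationMatrix
from .splice import (
    EVENT_TYPES,
    GenomeAnnotation,
    Junction,
    JunctionCountTable,
    SpliceEvent,
    Transcript,
    _classify_record,
    junction_id,
)

__all__ = [
    "PlantedEvent",
    "SimulationConfig",
    "TruthSet",
    "default_planted_events",
    "simulate_clonal_trajectories",
    "simulate_colonies",
    "simulate_junction_counts",
    "stream_rng",
]

_STREAMS = {"trajectories": 1, "colonies": 2, "junctions": 3}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named stream of a simulation seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def derive_truth_label(psi_control, psi_cloneA, psi_cloneB, threshold=2.0):
    """Truth label implied by planted PSIs under the 2% dPSI rule."""
    label = _classify_record(
        psi_cloneA - psi_control, psi_cloneB - psi_control,
        common_threshold=threshold, bias_threshold=threshold,
        require_sign_concordance=True,
    )
    return label


@dataclass(frozen=True)
class PlantedEvent:
    """One planted splicing event with per-group true PSIs (percent)."""

    event_id: str
    event_type: str
    psi_control: float
    psi_cloneA: float
    psi_cloneB: float
    truth_label: str
    strand: str = "+"
    cryptic_offset_nt: int = 15

    def __post_init__(self):
        for p in (self.psi_control, self.psi_cloneA, self.psi_cloneB):
            if not 0.0 <= p <= 100.0:
                raise InputError(f"{self.event_id}: PSI {p} outside [0, 100]")
        if self.event_type not in EVENT_TYPES:
            raise InputError(f"{self.event_id}: unknown event type {self.event_type!r}")
        implied = derive_truth_label(self.psi_control, self.psi_cloneA, self.psi_cloneB)
        if implied != self.truth_label:
            raise InputError(
                f"{self.event_id}: truth_label {self.truth_label!r} inconsistent with "
                f"planted PSIs (2% rule implies {implied!r})"
            )


def default_planted_events(
    n_common: int = 20,
    n_a_biased: int = 10,
    n_b_biased: int = 10,
    n_null: int = 10,
    dpsi: float = 15.0,
    psi_control: float = 30.0,
) -> list:
    """Planted event set: common, A-biased, B-biased and null events.

    Event types cycle through SE/A3SS/A5SS/RI/MXE; biased events shift one
    clone by ``dpsi`` percent while the other stays at control.
    """
    events = []
    specs = (
        [("common", dpsi, dpsi)] * n_common
        + [("A-biased", dpsi, 0.0)] * n_a_biased
        + [("B-biased", 0.0, dpsi)] * n_b_biased
        + [("null", 0.0, 0.0)] * n_null
    )
    for i, (label, da, db) in enumerate(specs):
        events.append(PlantedEvent(
            event_id=f"ev{i:04d}",
            event_type=EVENT_TYPES[i % len(EVENT_TYPES)],
            psi_control=psi_control,
            psi_cloneA=psi_control + da,
            psi_cloneB=psi_control + db,
            truth_label=label,
        ))
    return events


@dataclass
class SimulationConfig:
    """Generative parameters for a dual-clone dataset.

    Defaults describe the study conditions this package targets: two
    SF3B1-mutant clones in one marrow, a declining founder and an expanding
    competitor followed over 168 months, progenitor compartments skewed
    toward the fitter clone, clock-like mutation accrual at 18/year, and
    planted splicing shifts of 15 PSI percentage points.
    """

    seed: int
    n_clones: int = 2
    variant_ids: tuple = ("SF3B1-N626D", "SF3B1-K666N")
    selection_coeffs: tuple = (-0.52, 0.065)       # per year, relative to WT
    initial_fractions: tuple = (0.86, 0.092)       # cell fractions at t0
    sampling_times: tuple = (0, 12, 23, 36, 48, 57, 72, 84, 96, 108, 120, 144, 168)
    droplets_per_assay: int = 10_000
    detection_limit: float = 0.001
    compartments: tuple | None = None   # default: HSC mirrors bulk, MPP skewed
    colonies_per_compartment: int = 120
    mutation_rate_per_year: float = 18.0
    donor_ages: tuple = (66.0,)
    acquisition_time_bounds: tuple = (5.0, 45.0)
    acquisition_times: dict | None = None          # variant -> years, overrides bounds
    genotype_error_rate: float = 0.0
    event_truth: list | None = None                # defaults to default_planted_events()
    cells_per_clone: int = 100
    n_control_donors: int = 3
    mean_event_coverage: float = 50.0
    coverage_dispersion: float = 5.0               # negative binomial size

    def __post_init__(self):
        if self.seed is None:
            raise InputError("seed is mandatory")
        self.seed = int(self.seed)
        if self.n_clones < 1:
            raise InputError("need at least one mutant clone")
        if len(self.variant_ids) != self.n_clones:
            self.variant_ids = tuple(f"clone{i + 1}" for i in range(self.n_clones))
        for name, length in (("selection_coeffs", self.n_clones),
                             ("initial_fractions", self.n_clones)):
            if len(getattr(self, name)) != length:
                raise InputError(f"{name} must have one entry per clone")
        f0 = np.asarray(self.initial_fractions, dtype=float)
        if np.any(f0 < 0) or f0.sum() > 1:
            raise InputError("initial_fractions must be >= 0 and sum to <= 1")
        if self.mutation_rate_per_year < 0 or self.mean_event_coverage < 0:
            raise InputError("rates must be >= 0")
        if np.any(np.diff(self.sampling_times) <= 0):
            raise InputError("sampling_times must be strictly increasing")
        if self.droplets_per_assay <= 0:
            raise InputError("droplets_per_assay must be positive")
        if self.colonies_per_compartment < 0:
            raise InputError("negative colony count")
        if self.compartments is None:
            if self.n_clones == 2:
                self.compartments = (("HSC", (0.44, 0.50)), ("MPP", (0.06, 0.88)))
            else:
                self.compartments = (("HSC", tuple(self.initial_fractions)),)
        for name, fracs in self.compartments:
            fr = np.asarray(fracs, dtype=float)
            if len(fr) != self.n_clones or np.any(fr < 0) or fr.sum() > 1 + 1e-9:
                raise InputError(f"compartment {name!r}: clone fractions invalid")
        if self.event_truth is None:
            self.event_truth = default_planted_events()
        self.event_truth = [
            e if isinstance(e, PlantedEvent) else PlantedEvent(**e) for e in self.event_truth
        ]

    @classmethod
    def from_mapping(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        for key in ("variant_ids", "selection_coeffs", "initial_fractions",
                    "sampling_times", "donor_ages", "acquisition_time_bounds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "compartments" in raw:
            raw["compartments"] = tuple(
                (name, tuple(fr)) for name, fr in raw["compartments"]
            )
        return cls(**raw)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_mapping(json.load(fh))


@dataclass
class TruthSet:
    """Ground truth emitted alongside synthetic data, for recovery tests."""

    seed: int
    selection_coeffs: dict | None = None
    initial_fractions: dict | None = None
    clone_fractions: pd.DataFrame | None = None    # time_months x variant
    acquisition_times: dict | None = None          # variant -> years from birth
    trunk_mutations: dict | None = None            # variant -> [mutation ids]
    colony_clones: dict | None = None              # colony -> variant or "WT"
    events: list | None = None                     # list[PlantedEvent]
    event_defs: dict | None = None                 # event_id -> junction sets etc.

    def to_json(self, path) -> None:
        payload = {"seed": self.seed}
        for key in ("selection_coeffs", "initial_fractions", "acquisition_times",
                    "trunk_mutations", "colony_clones", "event_defs"):
            val = getattr(self, key)
            if val is not None:
                payload[key] = val
        if self.clone_fractions is not None:
            payload["clone_fractions"] = {
                "time_months": [float(t) for t in self.clone_fractions.index],
                "fractions": {c: [round(float(v), 6) for v in self.clone_fractions[c]]
                              for c in self.clone_fractions.columns},
            }
        if self.events is not None:
            payload["events"] = [asdict(e) for e in self.events]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        kwargs = {k: payload.get(k) for k in (
            "seed", "selection_coeffs", "initial_fractions", "acquisition_times",
            "trunk_mutations", "colony_clones", "event_defs")}
        if "clone_fractions" in payload:
            cf = payload["clone_fractions"]
            kwargs["clone_fractions"] = pd.DataFrame(
                cf["fractions"], index=pd.Index(cf["time_months"], name="time_months"))
        if "events" in payload:
            kwargs["events"] = [PlantedEvent(**e) for e in payload["events"]]
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# clonal VAF trajectories


def simulate_clonal_trajectories(config: SimulationConfig):
    """Replicator dynamics observed through ddPCR droplet sampling.

    Deterministic clone-fraction trajectories (closed form, WT at s = 0)
    are converted to heterozygous-diploid VAF = f/2 and observed as
    binomial(droplets, VAF) counts at each sampling time.

    Returns (list of VafTimeSeries, TruthSet).
    """
    rng = stream_rng(config.seed, "trajectories")
    times = np.asarray(config.sampling_times, dtype=float)
    frac = replicator_fractions(
        np.asarray(config.selection_coeffs, dtype=float),
        np.asarray(config.initial_fractions, dtype=float),
        times / 12.0,
    )
    vaf_true = frac / 2.0
    series = []
    for i, variant in enumerate(config.variant_ids):
        counts = rng.binomial(config.droplets_per_assay, vaf_true[:, i])
        vaf_obs = counts / config.droplets_per_assay
        series.append(VafTimeSeries(
            variant_id=variant,
            times=times,
            vaf=vaf_obs,
            droplets=np.full(len(times), config.droplets_per_assay),
            censored=vaf_obs < config.detection_limit,
        ))
    truth = TruthSet(
        seed=config.seed,
        selection_coeffs=dict(zip(config.variant_ids, map(float, config.selection_coeffs))),
        initial_fractions=dict(zip(config.variant_ids, map(float, config.initial_fractions))),
        clone_fractions=pd.DataFrame(
            frac, index=pd.Index(times, name="time_months"), columns=list(config.variant_ids)),
    )
    return series, truth


# ---------------------------------------------------------------------------
# colony genotypes


def simulate_colonies(config: SimulationConfig):
    """Compartment-wise colony genotype draws with clock-like mutation accrual.

    Per compartment, colony clone identities are multinomial in the clone
    fractions (remainder WT).  Every colony of a clone carries the clone's
    full trunk set (driver + Poisson(rate x t_acq) comutations, shared) plus
    private Poisson(rate x (age - t_acq)) mutations, so total burdens follow
    the molecular clock Poisson(rate x age).

    Returns (colony genotype DataFrame, BinaryMutationMatrix, TruthSet).
    """
    rng = stream_rng(config.seed, "colonies")
    rate = config.mutation_rate_per_year

    t_acq = {}
    lo, hi = config.acquisition_time_bounds
    for variant in config.variant_ids:
        if config.acquisition_times and variant in config.acquisition_times:
            t_acq[variant] = float(config.acquisition_times[variant])
        else:
            t_acq[variant] = float(rng.uniform(lo, hi))

    trunks = {}
    for variant in config.variant_ids:
        n_co = rng.poisson(rate * t_acq[variant])
        trunks[variant] = [variant] + [f"{variant}.trunk{j:03d}" for j in range(n_co)]

    rows = []          # (colony, compartment, age, clone)
    mut_sets = {}      # colony -> set of mutations
    for ci, (comp_name, fracs) in enumerate(config.compartments):
        age = float(config.donor_ages[min(ci, len(config.donor_ages) - 1)])
        probs = list(fracs) + [max(0.0, 1.0 - float(np.sum(fracs)))]
        counts = rng.multinomial(config.colonies_per_compartment, probs)
        labels = []
        for k, n in enumerate(counts):
            clone = config.variant_ids[k] if k < config.n_clones else "WT"
            labels.extend([clone] * n)
        rng.shuffle(labels)
        for j, clone in enumerate(labels):
            colony = f"{comp_name}.col{j:03d}"
            if clone == "WT":
                muts = set()
                n_priv = rng.poisson(rate * age)
            else:
                muts = set(trunks[clone])
                n_priv = rng.poisson(rate * max(0.0, age - t_acq[clone]))
            muts |= {f"{colony}.p{m:03d}" for m in range(n_priv)}
            rows.append((colony, comp_name, age, clone))
            mut_sets[colony] = muts

    colonies = [r[0] for r in rows]
    all_variants = sorted(set().union(*mut_sets.values())) if mut_sets else []
    col_index = {v: i for i, v in enumerate(all_variants)}
    arr = np.zeros((len(colonies), len(all_variants)), dtype=np.int8)
    for r, colony in enumerate(colonies):
        if mut_sets[colony]:
            arr[r, [col_index[v] for v in mut_sets[colony]]] = 1
    if config.genotype_error_rate > 0:
        # genotyping error as allele dropout: true presence calls are lost at
        # the given rate (symmetric flips would swamp a sparse matrix with
        # false positives, which colony ddPCR/WGS calling does not do)
        drops = (rng.random(arr.shape) < config.genotype_error_rate) & (arr == 1)
        arr = arr ^ drops
    mat = pd.DataFrame(arr, index=pd.Index(colonies, name="colony"),
                       columns=all_variants)

    meta = pd.DataFrame(rows, columns=["colony", "compartment", "age_years", "clone"])
    meta = meta.set_index("colony")
    for variant in config.variant_ids:
        meta[variant] = (mat[variant] == 1).astype(int) if variant in mat else 0

    matrix = BinaryMutationMatrix(
        matrix=mat,
        compartment=meta["compartment"],
        age_years=meta["age_years"],
    )
    truth = TruthSet(
        seed=config.seed,
        acquisition_times=t_acq,
        trunk_mutations={v: sorted(trunks[v]) for v in config.variant_ids},
        colony_clones=dict(zip(meta.index, meta["clone"])),
    )
    return meta, matrix, truth


# ---------------------------------------------------------------------------
# junction counts


_GENE_SPACING = 10_000


def _event_geometry(index: int, event: PlantedEvent):
    """Transcripts and inclusion/exclusion junctions realising one event.

    Each event gets its own gene on chromosome ``chrS``: exons E1/E2/E3 at
    fixed offsets, fully coding, with the cryptic isoform left unannotated
    (except MXE, where both isoforms are annotated).
    """
    o = index * _GENE_SPACING
    gene = f"gene{index:04d}"
    chrom, strand = "chrS", event.strand
    off = event.cryptic_offset_nt
    e1, e2, e3 = (o, o + 100), (o + 300, o + 400), (o + 600, o + 700)
    canon = Transcript(f"{gene}.t1", gene, chrom, strand, (e1, e2, e3), (e1, e2, e3))
    transcripts = [canon]
    etype = event.event_type

    if etype in ("A3SS", "A5SS"):
        share_start = (etype == "A3SS") == (strand == "+")
        canonical = Junction(chrom, e1[1], e2[0], strand)
        if share_start:
            cryptic = Junction(chrom, e1[1], e2[0] - off, strand)
        else:
            cryptic = Junction(chrom, e1[1] + off, e2[0], strand)
        inclusion, exclusion = [cryptic], [canonical]
    elif etype == "SE":
        inclusion = [Junction(chrom, e1[1], e2[0], strand),
                     Junction(chrom, e2[1], e3[0], strand)]
        exclusion = [Junction(chrom, e1[1], e3[0], strand)]
    elif etype == "RI":
        j = Junction(chrom, e1[1], e2[0], strand)
        inclusion = [Junction(chrom, e1[1], e2[0], strand, kind="intron_proxy")]
        exclusion = [j]
    elif etype == "MXE":
        e2b = (o + 450, o + 550)
        alt = Transcript(f"{gene}.t2", gene, chrom, strand, (e1, e2b, e3), (e1, e2b, e3))
        transcripts.append(alt)
        inclusion = [Junction(chrom, e1[1], e2[0], strand),
                     Junction(chrom, e2[1], e3[0], strand)]
        exclusion = [Junction(chrom, e1[1], e2b[0], strand),
                     Junction(chrom, e2b[1], e3[0], strand)]
    else:  # pragma: no cover - PlantedEvent validates event_type
        raise InputError(f"unknown event type {etype!r}")
    return transcripts, inclusion, exclusion


def simulate_junction_counts(config: SimulationConfig):
    """Per-cell junction counts with planted PSI shifts.

    For every cell and event: total coverage ~ negative binomial
    (mean ``mean_event_coverage``, size ``coverage_dispersion``); inclusion
    reads ~ binomial(coverage, PSI_true/100); reads on multi-junction paths
    are split multinomially so path sums are preserved.

    Returns (JunctionCountTable, GenomeAnnotation, TruthSet).
    """
    events = config.event_truth
    if not events:
        raise InputError("event truth table is empty")
    rng = stream_rng(config.seed, "junctions")

    transcripts, geometry = [], {}
    for i, ev in enumerate(events):
        tx, inc, exc = _event_geometry(i, ev)
        transcripts.extend(tx)
        geometry[ev.event_id] = (inc, exc)
    annotation = GenomeAnnotation(transcripts)

    junc_rows = {}
    for inc, exc in geometry.values():
        for j in inc + exc:
            junc_rows[junction_id(j)] = j
    junc_meta = pd.DataFrame(
        [{"chrom": j.chrom, "start": j.start, "end": j.end,
          "strand": j.strand, "kind": j.kind} for j in junc_rows.values()],
        index=pd.Index(junc_rows.keys(), name="junction_id"),
    )

    cells, cell_groups = [], []
    for g in ["cloneA", "cloneB"] + [f"NBM{d + 1}" for d in range(config.n_control_donors)]:
        for i in range(config.cells_per_clone):
            cells.append(f"{g}.c{i:03d}")
            cell_groups.append(g)

    n_cells = len(cells)
    counts = pd.DataFrame(0, index=pd.Index(cells, name="cell"),
                          columns=junc_meta.index, dtype=int)
    size = config.coverage_dispersion
    p_nb = size / (size + config.mean_event_coverage)
    psi_of = {"cloneA": "psi_cloneA", "cloneB": "psi_cloneB"}
    group_arr = np.asarray(cell_groups)

    for ev in events:
        inc, exc = geometry[ev.event_id]
        psi = np.empty(n_cells)
        for g in np.unique(group_arr):
            attr = psi_of.get(g, "psi_control")
            psi[group_arr == g] = getattr(ev, attr) / 100.0
        cov = rng.negative_binomial(size, p_nb, n_cells)
        inc_reads = rng.binomial(cov, psi)
        exc_reads = cov - inc_reads
        for path, reads in ((inc, inc_reads), (exc, exc_reads)):
            if len(path) == 1:
                counts[junction_id(path[0])] += reads
            else:
                split = rng.binomial(reads, 0.5)
                counts[junction_id(path[0])] += split
                counts[junction_id(path[1])] += reads - split

    table = JunctionCountTable(
        counts=counts,
        junctions=junc_meta,
        genotypes=pd.Series(cell_groups, index=counts.index, name="genotype"),
    )
    truth = TruthSet(
        seed=config.seed,
        events=list(events),
        event_defs={
            ev.event_id: {
                "gene_id": f"gene{i:04d}",
                "event_type": ev.event_type,
                "inclusion": [junction_id(j) for j in sorted(geometry[ev.event_id][0])],
                "exclusion": [junction_id(j) for j in sorted(geometry[ev.event_id][1])],
                "truth_label": ev.truth_label,
            }
            for i, ev in enumerate(events)
        },
    )
    return table, annotation, truth
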