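"""Synthetic input generators with known ground truth.

Every downstream stage of the package (trace quantification, symmetry
analysis, outcome classification, plate-count statistics, densitometry) is
exercisable on data produced here, with a :class:`TruthRecord` carrying the
planted values so estimators can be validated without any external data.

What is emulated, per generator:

* ``gen_trace_set`` — 4-channel peak-height Sanger traces over a shared
  template, with per-(position, base) lognormal context multipliers (the
  local sequence-dependent peak-height artefact the dual-control
  normalization exists to cancel; multipliers are frozen per template and
  shared by the sample and both controls) and zero-inflated skewed
  background noise on non-signal channels (gamma by default, lognormal as a
  deliberately misspecified alternative for the noise-model fitting stage).
* ``gen_assay_counts`` — paired selective/non-selective plate counts of the
  rapamycin-resistance editing assay, with beta-binomial overdispersion
  across biological replicates.
* ``gen_colony_reads`` — colony amplicon reads drawn from the four repair
  outcome categories (scarless SSTR, scarred SSTR, indel, wt) around a
  24-nt non-homologous central insert.
* ``gen_gel_lanes`` — restriction-digest band intensities (mass-
  proportional, as for SYBR staining) for planted site-wise digestion
  efficiencies.

All randomness flows through one ``numpy`` generator seeded from the spec;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .editquant import SNPSpec
from .traceio import BASES, Trace, reverse_complement, write_trace_tabular

#: 75-nt target region spanning break-relative positions -42..+32; the first
#: base is the normalization anchor ('A' at -42), the staggered-cut centre is
#: at relative position 0.
FKB12_TARGET = (
    "AAGACTGGCCAGACCGTGTTTGTGCACTACACGGGCACCCTGACCGACGGCAAGAAGTTCGACAGCTCCCGCGAC"
)
TARGET_REL_START = -42

#: Default SNP panel positions relative to the staggered-cut centre.
DEFAULT_PANEL_POSITIONS = (-32, -16, 0, 16, 32)

#: 24-nt non-homologous central insert carrying stop codons in all three
#: reading frames.
DEFAULT_INSERT = "CTAAGTAGTTGACATCGGATCCAA"

_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}

_CATEGORIES = ("scarless", "scarred", "indel", "wt")


@dataclasses.dataclass
class TruthRecord:
    """Planted ground truth for one batch of synthetic records."""

    kind: str
    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def default_template(trace_length: int = 500, target_position: int = 285) -> str:
    """Default trace template: random flanks around the 75-nt target.

    The target begins at 1-based ``target_position`` so the region of
    analysis falls inside the default 200-400 calibration window.  Flanks
    come from a fixed internal seed: the template is a constant of the
    default study design, not a per-run random quantity.
    """
    rng = np.random.default_rng(20211119)
    left = _random_seq(rng, target_position - 1)
    right = _random_seq(rng, trace_length - (target_position - 1) - len(FKB12_TARGET))
    return left + FKB12_TARGET + right


def default_snp_panel(positions=DEFAULT_PANEL_POSITIONS) -> list[SNPSpec]:
    """Transversion SNPs at the default panel positions."""
    panel = []
    for rel in positions:
        wt = FKB12_TARGET[rel - TARGET_REL_START]
        panel.append(SNPSpec(rel, wt, _TRANSVERSION[wt]))
    return panel


# ---------------------------------------------------------------------------
# traces


@dataclasses.dataclass
class SynthTraceSpec:
    """Study design for one synthetic trace set."""

    template_sequence: str = dataclasses.field(default_factory=default_template)
    target_position: int = 285  # 1-based template position of target start
    snp_panel: list[SNPSpec] = dataclasses.field(default_factory=default_snp_panel)
    true_editing: dict[int, float] = dataclasses.field(
        default_factory=lambda: {p: 0.3 for p in DEFAULT_PANEL_POSITIONS}
    )
    context_multiplier_sd: float = 0.25  # log-scale SD of peak multipliers
    noise_zero_prob: float = 0.35
    noise_shape: float = 1.5
    noise_scale: float = 0.004  # background peak proportions; mean ~0.6%
    noise_family: str = "gamma"  # or "lognormal" (misspecified alternative)
    signal_noise_cv: float = 0.0  # multiplicative CV on signal peaks
    base_amplitude: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.context_multiplier_sd < 0:
            raise ValueError("context_multiplier_sd must be nonnegative")
        if not 0.0 <= self.noise_zero_prob <= 1.0:
            raise ValueError("noise_zero_prob must lie in [0, 1]")
        if self.noise_shape <= 0 or self.noise_scale <= 0:
            raise ValueError("noise shape and scale must be positive")
        panel_rel = {s.rel_position for s in self.snp_panel}
        for s in self.snp_panel:
            idx = self._template_index(s.rel_position)
            if not 0 <= idx < len(self.template_sequence):
                raise ValueError(f"SNP position {s.rel_position} outside template")
            if self.template_sequence[idx] != s.wt_base:
                raise ValueError(
                    f"template base at relative position {s.rel_position} is "
                    f"{self.template_sequence[idx]!r}, not {s.wt_base!r}"
                )
        extra = set(self.true_editing) - panel_rel
        if extra:
            raise ValueError(f"true_editing positions not in panel: {sorted(extra)}")
        for f in self.true_editing.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("editing fractions must lie in [0, 1]")

    def _template_index(self, rel: int) -> int:
        return (self.target_position - 1) + (rel - TARGET_REL_START)

    @property
    def noise_off(self) -> bool:
        return self.noise_zero_prob >= 1.0


@dataclasses.dataclass
class TraceSetBundle:
    """Sample + control traces with their shared planted truth."""

    sample: Trace
    negative: Trace
    positives: dict[SNPSpec, Trace]
    truth: TruthRecord
    spec: SynthTraceSpec


def gen_trace_set(spec: SynthTraceSpec) -> TraceSetBundle:
    """Generate a sample trace, a negative control and per-SNP positive
    controls sharing one set of context multipliers.

    Before noise, the SNP channel's expected peak proportion at a panel
    position p equals ``true_editing[p] * multiplier``; the dual-control
    normalization recovers ``true_editing[p]`` exactly at zero noise.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(spec.template_sequence)
    if spec.context_multiplier_sd > 0:
        multipliers = np.exp(
            rng.normal(0.0, spec.context_multiplier_sd, size=(n, 4))
        )
    else:
        multipliers = np.ones((n, 4))

    panel_by_rel = {s.rel_position: s for s in spec.snp_panel}

    def build(name: str, editing: dict[int, float]) -> Trace:
        heights = np.zeros((n, 4))
        for i, base in enumerate(spec.template_sequence):
            bi = BASES.index(base)
            heights[i, bi] = spec.base_amplitude * multipliers[i, bi]
        for rel, f in editing.items():
            s = panel_by_rel[rel]
            i = spec._template_index(rel)
            wt_i = BASES.index(s.wt_base)
            snp_i = BASES.index(s.snp_base)
            heights[i, wt_i] = spec.base_amplitude * (1 - f) * multipliers[i, wt_i]
            heights[i, snp_i] = spec.base_amplitude * f * multipliers[i, snp_i]
        if spec.signal_noise_cv > 0:
            # replicate-to-replicate peak-height variability on signal peaks
            sigma = np.sqrt(np.log(1.0 + spec.signal_noise_cv**2))
            jitter = rng.lognormal(-0.5 * sigma**2, sigma, size=(n, 4))
            heights = np.where(heights > 0, heights * jitter, heights)
        if not spec.noise_off:
            active = rng.random(size=(n, 4)) >= spec.noise_zero_prob
            if spec.noise_family == "gamma":
                noise = rng.gamma(spec.noise_shape, spec.noise_scale, size=(n, 4))
            elif spec.noise_family == "lognormal":
                noise = rng.lognormal(
                    np.log(spec.noise_scale), spec.noise_shape, size=(n, 4)
                )
            else:
                raise ValueError(f"unknown noise family {spec.noise_family!r}")
            background = heights == 0
            heights = heights + np.where(
                active & background, spec.base_amplitude * noise, 0.0
            )
        called = "".join(BASES[i] for i in heights.argmax(axis=1))
        phred = np.full(n, 50)
        return Trace(name, called, heights, phred=phred, source_format="synthetic")

    sample = build("sample", dict(spec.true_editing))
    negative = build("negative_control", {})
    positives = {
        s: build(f"positive_{s.rel_position:+d}{s.snp_base}", {s.rel_position: 1.0})
        for s in spec.snp_panel
    }

    rows = []
    for s in spec.snp_panel:
        i = spec._template_index(s.rel_position)
        rows.append(
            {
                "rel_position": s.rel_position,
                "wt_base": s.wt_base,
                "snp_base": s.snp_base,
                "true_editing": spec.true_editing.get(s.rel_position, 0.0),
                "multiplier_wt": multipliers[i, BASES.index(s.wt_base)],
                "multiplier_snp": multipliers[i, BASES.index(s.snp_base)],
            }
        )
    truth = TruthRecord("traces", pd.DataFrame(rows))
    return TraceSetBundle(sample, negative, positives, truth, spec)


def write_trace_set(bundle: TraceSetBundle, outdir, format: str = "tabular") -> None:
    """Write all traces of a bundle plus the truth table to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traces = [bundle.sample, bundle.negative, *bundle.positives.values()]
    for trace in traces:
        if format == "tabular":
            write_trace_tabular(trace, outdir / f"{trace.name}.tsv")
        elif format == "abif":
            from .abif import write_abif

            write_abif(trace, outdir / f"{trace.name}.ab1")
        else:
            raise ValueError(f"unknown trace format {format!r}")
    bundle.truth.to_tsv(outdir / "truth_traces.tsv")


# ---------------------------------------------------------------------------
# plate counts


@dataclasses.dataclass
class SynthAssaySpec:
    """Design of a synthetic rapamycin-resistance plate-count experiment."""

    efficiencies: dict[str, float] = dataclasses.field(
        # Default: the terminally-modified-ssODN comparison layout
        # (editing-efficiency means in percent / 100).
        default_factory=lambda: {
            "unmodified": 0.084,
            "PS": 0.123,
            "LNA": 0.044,
            "LNA_5prime": 0.072,
            "LNA_3prime": 0.058,
            "dideoxy_3prime": 0.007,
            "PO_3prime": 0.053,
            "PO_5prime": 0.077,
        }
    )
    replicates: dict[str, int] | int = dataclasses.field(
        default_factory=lambda: {
            "unmodified": 7,
            "PS": 5,
            "LNA": 6,
            "LNA_5prime": 6,
            "LNA_3prime": 6,
            "dideoxy_3prime": 6,
            "PO_3prime": 5,
            "PO_5prime": 6,
        }
    )
    expected_colonies: float = 2000.0  # mean non-selective colonies per plate
    overdispersion: float = 0.002  # beta-binomial rho; 0 = pure binomial
    volume_selective: float = 450.0  # µL
    volume_nonselective: float = 450.0  # µL
    seed: int = 0

    def __post_init__(self) -> None:
        for g, e in self.efficiencies.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"efficiency for {g!r} outside [0, 1]")
        if self.volume_selective <= 0 or self.volume_nonselective <= 0:
            raise ValueError("plated volumes must be positive")
        if not 0.0 <= self.overdispersion < 1.0:
            raise ValueError("overdispersion must lie in [0, 1)")

    def n_replicates(self, genotype: str) -> int:
        if isinstance(self.replicates, int):
            return self.replicates
        return self.replicates[genotype]


def gen_assay_counts(spec: SynthAssaySpec) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate a plate-count table (one row per biological replicate).

    Non-selective counts are Poisson around the expected colony number; the
    number of cells committed to the selective plate follows from the plated
    volume ratio; resistant counts are (beta-)binomial in that number with
    the genotype's true efficiency as the mean success probability.
    """
    rng = np.random.default_rng(spec.seed)
    ratio = spec.volume_selective / spec.volume_nonselective
    rows = []
    for genotype, eff in spec.efficiencies.items():
        for rep in range(1, spec.n_replicates(genotype) + 1):
            n_ns = int(rng.poisson(spec.expected_colonies))
            n_cells_sel = int(round(n_ns * ratio))
            if eff in (0.0, 1.0) or spec.overdispersion == 0.0:
                p = eff
            else:
                nu = (1.0 - spec.overdispersion) / spec.overdispersion
                p = rng.beta(eff * nu, (1.0 - eff) * nu)
            n_sel = int(rng.binomial(n_cells_sel, p)) if n_cells_sel else 0
            rows.append(
                {
                    "genotype": genotype,
                    "replicate": rep,
                    "colonies_nonselective": n_ns,
                    "volume_nonselective": spec.volume_nonselective,
                    "colonies_selective": n_sel,
                    "volume_selective": spec.volume_selective,
                }
            )
    truth = TruthRecord(
        "assay",
        pd.DataFrame(
            {
                "genotype": list(spec.efficiencies),
                "true_efficiency_pct": [
                    100 * e for e in spec.efficiencies.values()
                ],
            }
        ),
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# colony amplicon reads


@dataclasses.dataclass
class ScarModel:
    """How scarred-repair junctions deviate from the perfect edit."""

    junction_del_max: int = 6
    junction_snp_prob: float = 0.5
    duplication_prob: float = 0.3
    duplication_max: int = 8
    partial_insert_min: int = 8  # shortest contiguous insert block retained


def default_wt_amplicon(length: int = 400, cut_site: int = 200) -> str:
    """Deterministic wild-type amplicon for read simulation."""
    rng = np.random.default_rng(20211120)
    return _random_seq(rng, length)


@dataclasses.dataclass
class SynthReadSpec:
    """Design of a synthetic colony-read experiment."""

    wt_amplicon: str = dataclasses.field(default_factory=default_wt_amplicon)
    insert_sequence: str = DEFAULT_INSERT
    cut_site: int = 200  # 0-based coordinate in wt_amplicon
    replaced_halfwidth: int = 12  # wt block replaced: cut_site +/- halfwidth
    category_mix: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "scarless": 0.80,
            "scarred": 0.05,
            "indel": 0.15,
            "wt": 0.00,
        }
    )
    n_reads: int = 50
    scar_model: ScarModel = dataclasses.field(default_factory=ScarModel)
    indel_sizes: tuple[int, ...] = tuple(range(2, 13))  # deletion sizes
    reverse_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.insert_sequence) != 24:
            raise ValueError("insert must be 24 nt")
        if set(self.category_mix) - set(_CATEGORIES):
            raise ValueError(f"categories must be among {_CATEGORIES}")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")
        if self.insert_sequence in self.wt_amplicon:
            raise ValueError("insert must not occur in the wt amplicon")

    @property
    def replace_start(self) -> int:
        return self.cut_site - self.replaced_halfwidth

    @property
    def replace_end(self) -> int:
        return self.cut_site + self.replaced_halfwidth

    @property
    def edited_amplicon(self) -> str:
        wt = self.wt_amplicon
        return wt[: self.replace_start] + self.insert_sequence + wt[self.replace_end :]


class ReadGenerationError(RuntimeError):
    """A scarred read stayed indistinguishable after bounded retries."""


def _make_scarred(spec: SynthReadSpec, rng: np.random.Generator) -> str:
    """Edited amplicon carrying a (possibly partial) insert plus a junction
    scar (deletion, SNP and/or local duplication)."""
    sm = spec.scar_model
    ins = spec.insert_sequence
    keep = int(rng.integers(sm.partial_insert_min, len(ins) + 1))
    start = int(rng.integers(0, len(ins) - keep + 1))
    partial = ins[start : start + keep]

    left = spec.wt_amplicon[: spec.replace_start]
    right = spec.wt_amplicon[spec.replace_end :]
    scarred = False
    # junction deletion on a random side
    if rng.random() < 0.7:
        d = int(rng.integers(1, sm.junction_del_max + 1))
        if rng.random() < 0.5:
            left = left[:-d]
        else:
            right = right[d:]
        scarred = True
    # local duplication of sequence flanking the junction
    if rng.random() < sm.duplication_prob:
        d = int(rng.integers(2, sm.duplication_max + 1))
        left = left + left[-d:]
        scarred = True
    # junction SNP just outside the insert
    if rng.random() < sm.junction_snp_prob or not scarred:
        i = len(left) - 1 - int(rng.integers(0, 5))
        left = left[:i] + _TRANSVERSION[left[i]] + left[i + 1 :]
    return left + partial + right


def _make_indel(spec: SynthReadSpec, rng: np.random.Generator) -> str:
    wt = spec.wt_amplicon
    size = int(rng.choice(spec.indel_sizes))
    if rng.random() < 0.2:  # small insertion of non-insert bases
        inserted = _random_seq(rng, min(size, 4))
        return wt[: spec.cut_site] + inserted + wt[spec.cut_site :]
    start = spec.cut_site - size // 2
    return wt[:start] + wt[start + size :]


def _longest_insert_run(read: str, insert: str, minimum: int) -> int:
    for k in range(len(insert), minimum - 1, -1):
        for i in range(len(insert) - k + 1):
            if insert[i : i + k] in read:
                return k
    return 0


def gen_colony_reads(
    spec: SynthReadSpec, max_retries: int = 10
) -> tuple[list[tuple[str, str]], TruthRecord]:
    """Generate colony amplicon reads as ``(read_id, sequence)`` pairs.

    Reads are constructed per category: scarless = the exact expected-edit
    amplicon; scarred = partial/whole insert plus junction scars; indel =
    cut-site indel without insert bases; wt = unmodified.  A scarred read
    that would be indistinguishable from another category at zero noise is
    regenerated (bounded retries).
    """
    rng = np.random.default_rng(spec.seed)
    cats = list(spec.category_mix)
    probs = np.array([spec.category_mix[c] for c in cats])
    assignments = rng.choice(cats, size=spec.n_reads, p=probs)
    min_run = spec.scar_model.partial_insert_min

    reads, rows = [], []
    for i, cat in enumerate(assignments):
        if cat == "scarless":
            seq = spec.edited_amplicon
        elif cat == "wt":
            seq = spec.wt_amplicon
        elif cat == "indel":
            seq = _make_indel(spec, rng)
        else:  # scarred
            for _ in range(max_retries):
                seq = _make_scarred(spec, rng)
                distinct = (
                    seq not in (spec.edited_amplicon, spec.wt_amplicon)
                    and _longest_insert_run(seq, spec.insert_sequence, min_run)
                    >= min_run
                )
                if distinct:
                    break
            else:
                raise ReadGenerationError(
                    "could not generate a distinguishable scarred read"
                )
        if rng.random() < spec.reverse_fraction:
            seq = reverse_complement(seq)
            strand = "-"
        else:
            strand = "+"
        read_id = f"colony_{i + 1:03d}"
        reads.append((read_id, seq))
        rows.append({"read_id": read_id, "category": cat, "strand": strand})
    truth = TruthRecord("reads", pd.DataFrame(rows))
    return reads, truth


def write_fasta(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f">{read_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# gel lanes


@dataclasses.dataclass
class BandModel:
    """Fragment layout and intensity model for one digest readout.

    Band intensity is proportional to DNA mass (molar amount x fragment
    length), as for an intercalating stain; ``noise_cv`` adds multiplicative
    lognormal noise per band.
    """

    amplicon_length: int = 1000
    cut_position_5prime: int = 474  # site at -26 relative to the break centre
    cut_position_3prime: int = 526  # site at +26
    enzyme_5prime: str = "BfaI"
    enzyme_3prime: str = "PvuII"
    gain: float = 1000.0
    noise_cv: float = 0.0


def gen_gel_lanes(
    true_eff_5prime: float,
    true_eff_3prime: float,
    band_model: Optional[BandModel] = None,
    seed: int = 0,
    replicates: int = 3,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate digest-lane band intensities for planted site efficiencies.

    Returns a long table with one row per band: replicate, site, enzyme,
    fragment_length, intensity, role (cut/uncut).
    """
    for e in (true_eff_5prime, true_eff_3prime):
        if not 0.0 <= e <= 1.0:
            raise ValueError("digestion efficiencies must lie in [0, 1]")
    bm = band_model or BandModel()
    rng = np.random.default_rng(seed)
    rows = []
    sites = [
        ("5prime", bm.enzyme_5prime, bm.cut_position_5prime, true_eff_5prime),
        ("3prime", bm.enzyme_3prime, bm.cut_position_3prime, true_eff_3prime),
    ]
    for rep in range(1, replicates + 1):
        for site, enzyme, cut, eff in sites:
            bands = [
                (bm.amplicon_length, (1.0 - eff) * bm.amplicon_length, "uncut"),
                (cut, eff * cut, "cut"),
                (bm.amplicon_length - cut, eff * (bm.amplicon_length - cut), "cut"),
            ]
            for length, mass, role in bands:
                intensity = mass * bm.gain
                if bm.noise_cv > 0 and intensity > 0:
                    sigma = np.sqrt(np.log(1.0 + bm.noise_cv**2))
                    intensity *= rng.lognormal(-0.5 * sigma**2, sigma)
                rows.append(
                    {
                        "replicate": rep,
                        "site": site,
                        "enzyme": enzyme,
                        "fragment_length": length,
                        "intensity": intensity,
                        "role": role,
                    }
                )
    truth = TruthRecord(
        "gel",
        pd.DataFrame(
            {
                "site": ["5prime", "3prime"],
                "enzyme": [bm.enzyme_5prime, bm.enzyme_3prime],
                "true_efficiency": [true_eff_5prime, true_eff_3prime],
            }
        ),
    )
    return pd.DataFrame(rows), truth
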