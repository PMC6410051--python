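"""Seed-reproducible synthetic inputs with known ground truth.

The generator emulates the statistical structure the analysis assumes rather
than raw sequencing reads: per-nt coverage is drawn negative-binomially (the
standard overdispersion model for sequencing depth) over synthetic transcript
architectures; IP enrichment is planted by multiplying the IP mean inside
chosen windows; differential expression, editing candidates (with one decoy
class per cascade filter), rMATS-style splicing tables and RBP site effects
are planted with explicit truth records.

Defaults mirror the study conditions: 200 genes at ~30x background coverage
with four-fold IP enrichment in 100-200 nt peaks; a -1.5 log2FC direct effect
of methyltransferase silencing on peak-bearing genes; 50 true editing sites
plus 10 decoys per filter class; a 37% editing loss in the silenced
condition; RBP effects of one log2 unit at 200 genes per group.  Fractions of
control peaks that remain common / become reduced, and the independent-peak
gene fraction, follow the study's reported proportions (75/3203, 37/3203,
89/1713 scaled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, IntervalMask
from .editing import READ_PRIME_DISCARD, EditingSite
from .tracks import CoverageTrack, make_tracks

__all__ = [
    "SimConfig",
    "RipSimulation",
    "simulate_rip",
    "simulate_conditions",
    "simulate_de",
    "simulate_editing",
    "simulate_editing_conditions",
    "simulate_splice_table",
    "simulate_rbp_sites",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with study-scale defaults."""

    n_genes: int = 200
    utr5_range: tuple[int, int] = (100, 300)
    cds_codons_range: tuple[int, int] = (100, 400)
    utr3_range: tuple[int, int] = (150, 500)
    max_exons: int = 4
    intron_range: tuple[int, int] = (200, 2000)
    noncoding_fraction: float = 0.1

    background_mean: float = 30.0
    dispersion: float = 0.3
    expression_sigma: float = 0.5
    read_length: int = 50

    peak_fraction: float = 0.2
    peak_fold: float = 4.0
    # planted peaks follow the caller's window lattice: widths 100-200 nt in
    # 50-nt steps, starts on the 50-nt grid (the scale the window scan sees)
    peak_width_range: tuple[int, int] = (100, 200)
    peak_grid: int = 50

    # silenced-condition structure (study proportions, scaled)
    common_fraction: float = 0.023
    reduced_fraction: float = 0.012
    independent_gene_fraction: float = 0.03
    reduced_control_fold: float = 12.0
    reduced_silenced_fold: float = 3.0

    de_direct_effect: float = -1.5
    de_noise_sd: float = 0.3

    n_true_sites: int = 50
    n_decoys_per_class: int = 10
    editing_ratio_range: tuple[float, float] = (0.2, 0.8)
    editing_reads_range: tuple[int, int] = (10, 50)
    editing_loss_fraction: float = 0.37
    true_alu_fraction: float = 0.72

    n_events_per_type: int = 60
    n_significant_se: int = 30

    n_rbps: int = 100
    rbp_group_n: int = 200
    rbp_effect: float = -1.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_fold < 1.0:
            raise ValueError("peak_fold must be >= 1")
        for name in ("n_genes", "n_true_sites", "n_decoys_per_class", "n_rbps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per simulation component."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class RipSimulation:
    models: dict[str, GeneModel]
    ip_tracks: dict[str, CoverageTrack]
    input_tracks: dict[str, CoverageTrack]
    truth: pd.DataFrame  # planted peaks: gene_id, transcript_id, start, end, fold
    genome: dict[str, str]


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mean + dispersion * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(float)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def make_models(config: SimConfig, rng: np.random.Generator) -> dict[str, GeneModel]:
    """Synthetic transcript architectures laid out along one chromosome."""
    models: dict[str, GeneModel] = {}
    cursor = 1000
    for i in range(config.n_genes):
        gid, tid = f"GSYN{i:05d}", f"TSYN{i:05d}"
        noncoding = rng.random() < config.noncoding_fraction
        u5 = int(rng.integers(*config.utr5_range))
        cds = 3 * int(rng.integers(*config.cds_codons_range))
        u3 = int(rng.integers(*config.utr3_range))
        length = u5 + cds + u3
        k = int(rng.integers(1, config.max_exons + 1))
        if k > 1:
            cuts = np.sort(rng.choice(np.arange(1, length), size=k - 1, replace=False))
            parts = np.diff(np.concatenate(([0], cuts, [length])))
        else:
            parts = np.array([length])
        exons = []
        pos = cursor
        for part in parts:
            exons.append((pos, pos + int(part)))
            pos += int(part) + int(rng.integers(*config.intron_range))
        strand = "+" if rng.random() < 0.5 else "-"
        models[gid] = GeneModel(
            gene_id=gid,
            transcript_id=tid,
            chrom="chrS",
            strand=strand,
            exons=tuple(exons),
            cds_start_tx=0 if noncoding else u5,
            cds_end_tx=0 if noncoding else u5 + cds,
            biotype="lincRNA" if noncoding else "protein_coding",
        )
        cursor = pos + 500
    return models


def make_genome(models: Mapping[str, GeneModel], rng: np.random.Generator) -> dict[str, str]:
    length = max(m.span[1] for m in models.values()) + 1000
    return {"chrS": _random_sequence(rng, length)}


def _plant_interval(
    config: SimConfig, rng: np.random.Generator, length: int
) -> tuple[int, int]:
    """A planted interval on the window lattice: width and start in 50-nt steps."""
    g = config.peak_grid
    lo, hi = config.peak_width_range
    width = g * int(rng.integers(lo // g, hi // g + 1))
    if width > length:
        raise ValueError(f"peak width {width} exceeds transcript length {length}")
    start = g * int(rng.integers(0, (length - width) // g + 1))
    return start, width


def plant_peaks(
    config: SimConfig, rng: np.random.Generator, models: Mapping[str, GeneModel]
) -> pd.DataFrame:
    """Choose peak-bearing genes and plant one enriched interval each."""
    gene_ids = sorted(models)
    n_peak = int(round(config.peak_fraction * len(gene_ids)))
    chosen = sorted(rng.permutation(gene_ids)[:n_peak])
    rows = []
    for gid in chosen:
        m = models[gid]
        start, width = _plant_interval(config, rng, m.transcript_length)
        rows.append(
            {
                "gene_id": gid,
                "transcript_id": m.transcript_id,
                "start": start,
                "end": start + width,
                "fold": config.peak_fold,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "start", "end", "fold"]
    )


def _tracks_for(
    config: SimConfig,
    rng: np.random.Generator,
    models: Mapping[str, GeneModel],
    truth: pd.DataFrame,
    factors: Mapping[str, float],
) -> tuple[dict[str, CoverageTrack], dict[str, CoverageTrack]]:
    folds = {
        r.transcript_id: (r.start, r.end, r.fold) for r in truth.itertuples()
    }
    ip_cov: dict[str, np.ndarray] = {}
    in_cov: dict[str, np.ndarray] = {}
    for gid in sorted(models):
        m = models[gid]
        base = config.background_mean * factors[gid]
        mean_ip = np.full(m.transcript_length, base)
        mean_in = np.full(m.transcript_length, base)
        planted = folds.get(m.transcript_id)
        if planted is not None:
            s, e, f = planted
            mean_ip[s:e] *= f
        ip_cov[m.transcript_id] = _nb(rng, mean_ip, config.dispersion)
        in_cov[m.transcript_id] = _nb(rng, mean_in, config.dispersion)
    return (
        make_tracks(ip_cov, config.read_length),
        make_tracks(in_cov, config.read_length),
    )


def simulate_rip(config: SimConfig) -> RipSimulation:
    """One condition: background NB coverage with planted IP enrichment."""
    rng = config.rng(1)
    models = make_models(config, rng)
    genome = make_genome(models, config.rng(2))
    truth = plant_peaks(config, rng, models)
    factors = {
        gid: float(f)
        for gid, f in zip(
            sorted(models),
            np.exp(rng.normal(0.0, config.expression_sigma, size=len(models))),
        )
    }
    ip, ctrl = _tracks_for(config, config.rng(3), models, truth, factors)
    return RipSimulation(models, ip, ctrl, truth, genome)


def simulate_conditions(
    config: SimConfig,
) -> tuple[RipSimulation, RipSimulation, pd.DataFrame]:
    """Control and silenced RIP experiments over shared models.

    Control peaks are planted per config; in the silenced condition a small
    fraction stay common (full fold), a small fraction are reduced (lower
    fold from a higher control fold), the rest disappear, and a few genes
    without control peaks gain silenced-only (enzyme-independent) peaks.
    Returns (control, silenced, peak-level truth with class labels).
    """
    rng = config.rng(1)
    models = make_models(config, rng)
    genome = make_genome(models, config.rng(2))
    truth = plant_peaks(config, rng, models)

    n = len(truth)
    classes = np.array(["lost"] * n, dtype=object)
    order = rng.permutation(n)
    n_common = int(round(config.common_fraction * n))
    n_reduced = int(round(config.reduced_fraction * n))
    classes[order[:n_common]] = "common"
    classes[order[n_common:n_common + n_reduced]] = "reduced"
    truth = truth.assign(peak_class=classes)

    non_peak = sorted(set(models) - set(truth["gene_id"]))
    n_indep = int(round(config.independent_gene_fraction * len(models)))
    indep_rows = []
    for gid in sorted(rng.permutation(non_peak)[:n_indep]):
        m = models[gid]
        start, width = _plant_interval(config, rng, m.transcript_length)
        indep_rows.append(
            {
                "gene_id": gid,
                "transcript_id": m.transcript_id,
                "start": start,
                "end": start + width,
                "fold": config.peak_fold,
                "peak_class": "independent",
            }
        )
    indep = pd.DataFrame(
        indep_rows,
        columns=["gene_id", "transcript_id", "start", "end", "fold", "peak_class"],
    )

    factors = {
        gid: float(f)
        for gid, f in zip(
            sorted(models),
            np.exp(rng.normal(0.0, config.expression_sigma, size=len(models))),
        )
    }

    ctrl_truth = truth.copy()
    ctrl_truth.loc[ctrl_truth["peak_class"] == "reduced", "fold"] = (
        config.reduced_control_fold
    )
    sil_truth = pd.concat(
        [truth[truth["peak_class"] != "lost"], indep], ignore_index=True
    )
    sil_truth = sil_truth.copy()
    sil_truth.loc[sil_truth["peak_class"] == "reduced", "fold"] = (
        config.reduced_silenced_fold
    )

    ip_c, in_c = _tracks_for(config, config.rng(3), models, ctrl_truth, factors)
    ip_s, in_s = _tracks_for(config, config.rng(4), models, sil_truth, factors)
    control = RipSimulation(models, ip_c, in_c, ctrl_truth, genome)
    silenced = RipSimulation(models, ip_s, in_s, sil_truth, genome)
    full_truth = pd.concat([ctrl_truth, indep], ignore_index=True)
    return control, silenced, full_truth


def simulate_de(
    config: SimConfig,
    truth: pd.DataFrame,
    models: Mapping[str, GeneModel],
) -> pd.DataFrame:
    """Differential-expression table with planted direct effects.

    Genes carrying methyltransferase-dependent peaks (classes lost/reduced,
    or all planted genes when the truth has no class column) are shifted by
    ``de_direct_effect``; all other genes are centered at zero.  Adjusted
    p-values are small exactly for genes whose drawn |log2FC| clears the
    1.5-fold line, so a zero effect yields a null table.
    """
    rng = config.rng(5)
    if "peak_class" in truth.columns:
        direct = set(truth.loc[truth["peak_class"].isin(["lost", "reduced"]), "gene_id"])
        peak_genes = set(truth["gene_id"])
    else:
        direct = set(truth["gene_id"])
        peak_genes = direct
    rows = []
    lfc_cut = np.log2(1.5)
    for gid in sorted(models):
        m = models[gid]
        shift = config.de_direct_effect if gid in direct else 0.0
        lfc = shift + rng.normal(0.0, config.de_noise_sd)
        if abs(lfc) > lfc_cut:
            padj = 10.0 ** -rng.uniform(3, 8)
        else:
            padj = rng.uniform(0.05, 1.0)
        base = float(np.exp(rng.normal(np.log(10.0), 1.0)))
        if m.biotype == "lincRNA":
            base *= 0.3
        if gid in peak_genes:
            base *= 2.5  # m6A-marked transcripts are the more abundant ones
        rows.append(
            {
                "gene_id": gid,
                "log2_fold_change": lfc,
                "p_adjusted": padj,
                "biotype": m.biotype,
                "abundance_control": base,
                "abundance_silenced": base * 2.0 ** lfc,
                "m6a": gid in peak_genes,
            }
        )
    return pd.DataFrame(rows)


# -- editing -------------------------------------------------------------------

DECOY_CLASSES = (
    "snp",
    "low_support",
    "simple_repeat",
    "splice_junction",
    "homopolymer",
    "similarity",
    "first_six",
)
EXPECTED_FILTER = {
    "true": "pass",
    "snp": "snp",
    "low_support": "support",
    "simple_repeat": "simple_repeat",
    "splice_junction": "splice_junction",
    "homopolymer": "homopolymer",
    "similarity": "similarity",
    "first_six": "support",
}


def simulate_editing(
    config: SimConfig,
) -> tuple[list[EditingSite], dict[str, IntervalMask], dict[str, str], pd.DataFrame]:
    """True editing sites plus one decoy cohort per cascade filter.

    Every decoy violates exactly the filter of its class; true sites avoid
    all masks and carry >= 3 post-discount alt reads at ratio within the
    configured range.  Returns (sites, masks, reference, truth).
    """
    rng = config.rng(6)
    spacing = 100
    total_sites = config.n_true_sites + len(DECOY_CLASSES) * config.n_decoys_per_class
    chrom = "chrE"
    seq = np.frombuffer((b"ACGT" * ((total_sites * spacing + 200) // 4 + 1)), dtype=np.uint8).copy()

    masks = {
        name: IntervalMask(name)
        for name in ("snp", "alu", "simple_repeat", "splice_junction", "similarity")
    }
    sites: list[EditingSite] = []
    truth_rows = []

    def supported_site(pos: int) -> EditingSite:
        total = int(rng.integers(*config.editing_reads_range))
        ratio = float(rng.uniform(*config.editing_ratio_range))
        n_alt = max(3, int(np.ceil(ratio * total)))
        n_alt = min(n_alt, total)
        offsets = tuple(
            int(o)
            for o in rng.integers(READ_PRIME_DISCARD, config.read_length, size=n_alt)
        )
        a_to_i = rng.random() < 0.8
        ref, alt = ("A", "G") if a_to_i else ("C", "T")
        seq[pos] = ord(ref)
        return EditingSite(
            chrom=chrom, pos=pos, ref_base=ref, alt_base=alt, strand="+",
            total_reads=total, alt_read_offsets=offsets,
        )

    def add(site: EditingSite, klass: str) -> None:
        sites.append(site)
        truth_rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "klass": klass,
                "expected_filter": EXPECTED_FILTER[klass],
            }
        )

    idx = 0
    for _ in range(config.n_true_sites):
        pos = 50 + idx * spacing
        idx += 1
        site = supported_site(pos)
        if rng.random() < config.true_alu_fraction:
            masks["alu"].add(chrom, pos - 20, pos + 20)
        add(site, "true")

    for klass in DECOY_CLASSES:
        for _ in range(config.n_decoys_per_class):
            pos = 50 + idx * spacing
            idx += 1
            if klass == "low_support":
                total = int(rng.integers(20, 40))
                offsets = tuple(
                    int(o) for o in rng.integers(READ_PRIME_DISCARD, 50, size=2)
                )
                seq[pos] = ord("A")
                site = EditingSite(
                    chrom=chrom, pos=pos, ref_base="A", alt_base="G", strand="+",
                    total_reads=total, alt_read_offsets=offsets,
                )
            elif klass == "first_six":
                total = int(rng.integers(20, 40))
                offsets = tuple(int(o) for o in rng.integers(0, READ_PRIME_DISCARD, size=4))
                seq[pos] = ord("A")
                site = EditingSite(
                    chrom=chrom, pos=pos, ref_base="A", alt_base="G", strand="+",
                    total_reads=total, alt_read_offsets=offsets,
                )
            else:
                site = supported_site(pos)
            if klass == "snp":
                masks["snp"].add(chrom, pos, pos + 1)
            elif klass == "simple_repeat":
                masks["simple_repeat"].add(chrom, pos - 5, pos + 5)
            elif klass == "splice_junction":
                masks["splice_junction"].add(chrom, pos + 4, pos + 5)
            elif klass == "homopolymer":
                seq[pos - 2:pos + 3] = ord(site.ref_base)
            elif klass == "similarity":
                masks["similarity"].add(chrom, pos - 10, pos + 10)
            add(site, klass)

    reference = {chrom: seq.tobytes().decode()}
    truth = pd.DataFrame(truth_rows)
    return sites, masks, reference, truth


def simulate_editing_conditions(
    config: SimConfig,
) -> tuple[list[EditingSite], list[EditingSite]]:
    """Passing true sites in control vs silenced (a seeded fraction dropped)."""
    sites, masks, reference, truth = simulate_editing(config)
    passing = [
        s
        for s, k in zip(sites, truth["klass"])
        if k == "true"
    ]
    rng = config.rng(7)
    keep_n = int(round(len(passing) * (1.0 - config.editing_loss_fraction)))
    kept_idx = sorted(rng.permutation(len(passing))[:keep_n])
    silenced = [passing[i] for i in kept_idx]
    return passing, silenced


# -- splicing ------------------------------------------------------------------


def simulate_splice_table(
    config: SimConfig,
    gene_ids: Sequence[str] | None = None,
    m6a_genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """rMATS-format event table with planted significant SE events.

    Significant SE events carry FDR < 0.05, |delta PSI| >= 0.1 (inclusion
    higher in the silenced condition) and replicate counts >= 10; all other
    events fail at least one filter.  Returns (table, truth).
    """
    rng = config.rng(8)
    genes = list(gene_ids) if gene_ids else [f"GSYN{i:05d}" for i in range(200)]
    m6a = set(m6a_genes) if m6a_genes else set(genes[: len(genes) // 5])
    m6a_list = sorted(m6a) or genes
    rows, truth_rows = [], []
    eid = 0
    for etype in ("SE", "RI", "A5SS", "A3SS", "MXE"):
        n_sig = config.n_significant_se if etype == "SE" else 0
        for j in range(config.n_events_per_type):
            significant = j < n_sig
            if significant:
                fdr = 10.0 ** -rng.uniform(3, 6)
                dpsi = -float(rng.uniform(0.1, 0.4))  # inclusion up when silenced
                counts = rng.integers(12, 60, size=8)
                gene = m6a_list[int(rng.integers(0, len(m6a_list)))] if rng.random() < 0.8 else genes[int(rng.integers(0, len(genes)))]
            else:
                fdr = float(rng.uniform(0.2, 1.0))
                dpsi = float(rng.uniform(-0.03, 0.03))
                counts = rng.integers(12, 60, size=8)
                if rng.random() < 0.2:
                    counts[rng.integers(0, 8)] = int(rng.integers(0, 9))
                gene = genes[int(rng.integers(0, len(genes)))]
            psi1 = float(np.clip(rng.uniform(0.3, 0.7), 0, 1))
            psi2 = float(np.clip(psi1 - dpsi, 0, 1))
            jit = rng.uniform(-0.02, 0.02, size=4)
            exon_start = 5000 + eid * 1000
            rows.append(
                {
                    "ID": eid,
                    "event_type": etype,
                    "GeneID": gene,
                    "geneSymbol": gene,
                    "chr": "chrS",
                    "strand": "+",
                    "exonStart_0base": exon_start,
                    "exonEnd": exon_start + 150,
                    "IJC_SAMPLE_1": f"{counts[0]},{counts[1]}",
                    "SJC_SAMPLE_1": f"{counts[2]},{counts[3]}",
                    "IJC_SAMPLE_2": f"{counts[4]},{counts[5]}",
                    "SJC_SAMPLE_2": f"{counts[6]},{counts[7]}",
                    "IncLevel1": f"{np.clip(psi1 + jit[0], 0, 1):.4f},{np.clip(psi1 + jit[1], 0, 1):.4f}",
                    "IncLevel2": f"{np.clip(psi2 + jit[2], 0, 1):.4f},{np.clip(psi2 + jit[3], 0, 1):.4f}",
                    "IncLevelDifference": dpsi,
                    "PValue": fdr / 2,
                    "FDR": fdr,
                }
            )
            truth_rows.append({"ID": eid, "event_type": etype, "significant": significant})
            eid += 1
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# -- RBP cooperation -----------------------------------------------------------


def simulate_rbp_sites(
    config: SimConfig,
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], pd.DataFrame]:
    """Per-RBP expression-change samples for site-bearing vs site-free genes.

    Labels cycle stabilizer/destabilizer/neutral; a stabilizer shifts the
    site-bearing group by ``rbp_effect`` (negative: silencing hits its
    targets harder), a destabilizer by the opposite sign.
    """
    rng = config.rng(9)
    labels = ["stabilizer", "destabilizer", "neutral"]
    data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    rows = []
    n = config.rbp_group_n
    for i in range(config.n_rbps):
        label = labels[i % 3]
        shift = {
            "stabilizer": config.rbp_effect,
            "destabilizer": -config.rbp_effect,
            "neutral": 0.0,
        }[label]
        with_site = rng.normal(shift, 1.0, size=n)
        without = rng.normal(0.0, 1.0, size=n)
        name = f"RBP{i:03d}"
        data[name] = (with_site, without)
        rows.append({"rbp": name, "label": label, "shift": shift})
    return data, pd.DataFrame(rows)
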