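"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of the study's two
data types — junction-array probe intensities (log-normal multiplicative
noise, per-probe affinities, include/skip/constitutive probe sets, a
large pool of unexpressed genes forming the detection background) and
RNA-seq expression tables (overdispersed counts turned into CPM) — plus
random transcriptomes carrying planted QREs and cassette-exon loci with
ACUAA motifs planted at known intronic offsets.

Background sequence is i.i.d. uniform over ACGT, which makes chance
motif rates analytically computable (4^-5 per position for a 5-mer).
Every planted quantity is recorded in :class:`PlantedTruth` so
parameter-recovery tests never have to re-derive the truth from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qremap.io import AnnotationRecord
from qremap.qre import HALF1_LEN, HALF2_LEN, reverse_complement

ALPHABET = np.array(list("ACGT"))


@dataclass
class NoiseModel:
    """Noise structure of the junction-array generator.

    ``probe_sd_log2``: sd of the per-measurement log2 intensity noise.
    ``probe_affinity_sd``: log2 sd of the per-probe multiplicative
    affinity (constant across arrays).  ``cpm_dispersion``: dispersion
    of the gamma-Poisson count noise in the expression generator.
    """

    probe_sd_log2: float = 0.25
    probe_affinity_sd: float = 0.25
    cpm_dispersion: float = 0.1

    def __post_init__(self) -> None:
        if min(self.probe_sd_log2, self.probe_affinity_sd, self.cpm_dispersion) < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class PlantedTruth:
    """The truth channel: everything the generators planted.

    ``qre_positions``: gene -> [(mature offset of half-site 1, spacer
    length)].  ``event_effects``: event -> dict with the reference and
    experimental inclusion fractions and the signed log2 inclusion-odds
    effect.  ``expression_shift``: gene -> true log2 fold change.
    ``qre_targets``: gene -> bool target flag (expression generator).
    ``map_offsets``: set label -> [(chrom, sense offset of the planted
    motif start from the exon boundary; negative = upstream intron)].
    """

    qre_positions: dict = field(default_factory=dict)
    event_effects: dict = field(default_factory=dict)
    expression_shift: dict = field(default_factory=dict)
    qre_targets: dict = field(default_factory=dict)
    map_offsets: dict = field(default_factory=dict)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(ALPHABET[rng.integers(0, 4, size=n)])


def _make_qre_site(rng: np.random.Generator) -> tuple[str, int]:
    """A random sequence realisation of UACUAAY N1-20 UAAY (DNA alphabet)."""
    spacer_len = int(rng.integers(1, 21))
    y1 = str(rng.choice(["C", "T"]))
    y2 = str(rng.choice(["C", "T"]))
    site = "TACTAA" + y1 + _rand_seq(rng, spacer_len) + "TAA" + y2
    return site, spacer_len


def gen_transcriptome(
    n_genes: int,
    qre_fraction: float,
    seed: int,
    exon_len_range: tuple[int, int] = (100, 300),
    intron_len_range: tuple[int, int] = (100, 400),
) -> tuple[list[AnnotationRecord], dict[str, str], PlantedTruth]:
    """Random multi-exon genes, a fraction carrying planted QREs.

    Each gene sits on its own chromosome and has 1-3 transcripts of
    2-10 exons; the longest transcript uses every exon, the others
    random subsets.  For a ``qre_fraction`` subset of genes, 1-3 QRE
    sites are written into exons of the longest transcript (wholly
    inside one exon) and their mature-sequence offsets recorded.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= qre_fraction <= 1:
        raise ValueError(f"qre_fraction outside [0,1]: {qre_fraction}")
    rng = np.random.default_rng(seed)
    n_qre_genes = int(round(qre_fraction * n_genes))
    qre_gene_idx = set(rng.choice(n_genes, size=n_qre_genes, replace=False).tolist())

    annotation: list[AnnotationRecord] = []
    genome: dict[str, str] = {}
    truth = PlantedTruth()

    for g in range(n_genes):
        gene_id = f"gene{g:04d}"
        chrom = f"chr_{gene_id}"
        strand = str(rng.choice(["+", "-"]))
        n_exons = int(rng.integers(2, 11))
        exon_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1, size=n_exons)
        intron_lens = rng.integers(intron_len_range[0], intron_len_range[1] + 1, size=n_exons - 1)
        pos = 0
        exons: list[tuple[int, int]] = []
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        seq = list(_rand_seq(rng, pos))

        # transcripts: t0 = all exons (the longest); extras are subsets
        n_tx = int(rng.integers(1, 4))
        tx_exons = {f"{gene_id}_t0": list(range(n_exons))}
        for t in range(1, n_tx):
            k = int(rng.integers(2, n_exons + 1)) if n_exons > 2 else 2
            k = min(k, n_exons - 1) if n_exons > 2 else 2
            if k >= n_exons:
                continue
            pick = sorted(rng.choice(n_exons, size=k, replace=False).tolist())
            tx_exons[f"{gene_id}_t{t}"] = pick

        # plant QREs wholly inside exons of the longest transcript
        truth.qre_positions[gene_id] = []
        if g in qre_gene_idx:
            used: list[tuple[int, int]] = []
            n_sites = int(rng.integers(1, 4))
            for _ in range(n_sites):
                site, spacer_len = _make_qre_site(rng)
                site_len = len(site)
                for _attempt in range(50):
                    ei = int(rng.integers(0, n_exons))
                    es, ee = exons[ei]
                    if ee - es <= site_len:
                        continue
                    off = int(rng.integers(0, ee - es - site_len + 1))
                    g0, g1 = es + off, es + off + site_len
                    if any(not (g1 <= a or g0 >= b) for a, b in used):
                        continue
                    used.append((g0, g1))
                    if strand == "+":
                        seq[g0:g1] = list(site)
                        mature_off = sum(e - s for s, e in exons[:ei]) + off
                    else:
                        seq[g0:g1] = list(reverse_complement(site))
                        # transcription order is reversed; offset within the
                        # exon is measured from its genomic end
                        mature_off = sum(e - s for s, e in exons[ei + 1 :]) + (ee - g1)
                    truth.qre_positions[gene_id].append((mature_off, spacer_len))
                    break

        genome[chrom] = "".join(seq)
        for tx_id, idxs in tx_exons.items():
            order = idxs if strand == "+" else list(reversed(idxs))
            for rank, ei in enumerate(order):
                annotation.append(
                    AnnotationRecord(
                        chrom=chrom,
                        start=exons[ei][0],
                        end=exons[ei][1],
                        strand=strand,
                        gene_id=gene_id,
                        transcript_id=tx_id,
                        exon_index=rank,
                    )
                )
    return annotation, genome, truth


def gen_junction_array(
    n_events: int,
    n_null: int,
    effect_log2: float,
    replicates: int,
    noise: NoiseModel,
    seed: int,
    n_unexpressed: int | None = None,
    probes_per_set: tuple[int, int] = (3, 8),
    conditions: tuple[str, str] = ("ref", "exp"),
    expressed_log2: float = 10.0,
    background_log2: float = 6.0,
    baseline_sd_log2: float = 1.0,
    gc_slope: float = 2.0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Junction-array probe table with planted splicing effects.

    ``n_events`` expressed events get a signed log2 inclusion-odds
    change of ``effect_log2`` between the two conditions; ``n_null``
    expressed events get none.  ``n_unexpressed`` additional events
    (default 30x the expressed count) sit at background intensity and
    provide the empirical-CDF detection background: presence calling
    ranks a probe against all probes of its GC stratum, so the chip
    must be dominated by probes of unexpressed genes for expressed
    probe sets to reach small empirical p-values, as on a genome-scale
    chip where any one cell type expresses a minority of probe sets.
    Pass 0 when only the KW machinery is exercised.  Intensity model per probe and array:
    baseline x isoform fraction x GC term x probe affinity x log-normal
    noise.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2 (the KW test needs groups)")
    if n_events < 0 or n_null < 0:
        raise ValueError("event counts must be >= 0")
    rng = np.random.default_rng(seed)
    if n_unexpressed is None:
        n_unexpressed = 30 * (n_events + n_null)
    ref_cond, exp_cond = conditions
    sample_cols = [
        f"sample:{c}:{r + 1}" for c in (ref_cond, exp_cond) for r in range(replicates)
    ]
    cond_of_col = [ref_cond] * replicates + [exp_cond] * replicates

    truth = PlantedTruth()
    rows: list[dict] = []
    kinds = ["affected"] * n_events + ["null"] * n_null + ["unexpressed"] * n_unexpressed
    for e, kind in enumerate(kinds):
        event_id = f"ev{e:05d}"
        event_type = str(rng.choice(["CE", "alt5", "alt3", "RI"], p=[0.6, 0.15, 0.15, 0.1]))
        expressed = kind != "unexpressed"
        base = expressed_log2 if expressed else background_log2
        g = base + (rng.normal(0.0, baseline_sd_log2) if baseline_sd_log2 > 0 else 0.0)
        psi_ref = float(rng.uniform(0.3, 0.7))
        if kind == "affected":
            sign = int(rng.choice([-1, 1]))
            delta = sign * effect_log2
        else:
            sign, delta = 0, 0.0
        logit_ref = np.log2(psi_ref / (1 - psi_ref))
        psi_exp = float(1.0 / (1.0 + 2.0 ** -(logit_ref + delta)))
        truth.event_effects[event_id] = {
            "kind": kind,
            "psi_ref": psi_ref,
            "psi_exp": psi_exp,
            "effect_log2": delta,
        }
        psi = {ref_cond: psi_ref, exp_cond: psi_exp}
        for role in ("include", "skip", "constitutive"):
            n_probes = int(rng.integers(probes_per_set[0], probes_per_set[1] + 1))
            probeset_id = f"{event_id}_{role}"
            for p in range(n_probes):
                gc = float(rng.uniform(0.3, 0.7))
                affinity = (
                    float(rng.normal(0.0, noise.probe_affinity_sd))
                    if noise.probe_affinity_sd > 0
                    else 0.0
                )
                row = {
                    "probe_id": f"{probeset_id}_p{p}",
                    "probeset_id": probeset_id,
                    "event_id": event_id,
                    "event_type": event_type,
                    "role": role,
                    "gc": gc,
                }
                for col, cond in zip(sample_cols, cond_of_col):
                    if role == "include":
                        frac = np.log2(psi[cond])
                    elif role == "skip":
                        frac = np.log2(1 - psi[cond])
                    else:
                        frac = 0.0
                    eps = (
                        float(rng.normal(0.0, noise.probe_sd_log2))
                        if noise.probe_sd_log2 > 0
                        else 0.0
                    )
                    row[col] = float(2.0 ** (g + frac + gc_slope * (gc - 0.5) + affinity + eps))
                rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=["probe_id", "probeset_id", "event_id", "event_type", "role", "gc"] + sample_cols,
    )
    return df, truth


def gen_expression_table(
    n_genes: int,
    qre_fraction: float,
    shift_log2: float,
    seed: int,
    noise: NoiseModel | None = None,
    low_fraction: float = 0.15,
    na_fraction: float = 0.05,
    bio_sd_log2: float = 0.3,
    conditions: tuple[str, str] = ("ref", "exp"),
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Two-condition expression table with a planted QRE-target shift.

    QRE-flagged genes' log2 fold-change distribution is shifted by
    ``shift_log2`` relative to the non-flagged genes; all genes carry
    biological log-normal variation plus gamma-Poisson count noise.  A
    ``low_fraction`` of genes is drawn below the expression floor and a
    ``na_fraction`` gets an NA QRE annotation.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if not 0 <= qre_fraction <= 1:
        raise ValueError(f"qre_fraction outside [0,1]: {qre_fraction}")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    ref_cond, exp_cond = conditions

    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    is_target = np.zeros(n_genes, dtype=bool)
    is_target[rng.choice(n_genes, size=int(round(qre_fraction * n_genes)), replace=False)] = True
    is_low = rng.random(n_genes) < low_fraction
    mu = np.where(is_low, rng.normal(-3.0, 1.0, n_genes), rng.normal(5.0, 2.0, n_genes))
    true_lfc = np.where(is_target, shift_log2, 0.0) + (
        rng.normal(0.0, bio_sd_log2, n_genes) if bio_sd_log2 > 0 else 0.0
    )

    def _counts(log2_mean: np.ndarray) -> np.ndarray:
        mean = 2.0**log2_mean
        if noise.cpm_dispersion > 0:
            shape = 1.0 / noise.cpm_dispersion
            lam = rng.gamma(shape, mean / shape)
        else:
            lam = mean
        return rng.poisson(lam)

    counts = pd.DataFrame(
        {
            f"count:{ref_cond}": _counts(mu - true_lfc / 2),
            f"count:{exp_cond}": _counts(mu + true_lfc / 2),
        },
        index=gene_ids,
    )
    from qremap.expression import cpm_quantile_normalize

    cpms = cpm_quantile_normalize(counts)
    qre_count = np.where(is_target, 1 + rng.poisson(1.0, n_genes), 0).astype(object)
    na_idx = rng.random(n_genes) < na_fraction
    qre_count[na_idx] = pd.NA

    df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            f"cpm:{ref_cond}": cpms[f"count:{ref_cond}"].to_numpy(),
            f"cpm:{exp_cond}": cpms[f"count:{exp_cond}"].to_numpy(),
            "qre_count": pd.array(qre_count, dtype="Int64"),
        }
    )
    truth = PlantedTruth(
        expression_shift={g: float(l) for g, l in zip(gene_ids, true_lfc)},
        qre_targets={g: bool(t) for g, t in zip(gene_ids, is_target)},
    )
    return df, truth


def gen_rna_map_set(
    n_act: int,
    n_rep: int,
    n_bg: int,
    offset_nt: int,
    intron_len: int,
    seed: int,
    window: int = 50,
    motif: str = "ACTAA",
    exon_len: int = 120,
    flank_exon_len: int = 100,
) -> tuple[pd.DataFrame, list[AnnotationRecord], dict[str, str], PlantedTruth]:
    """Cassette-exon loci with ACUAA planted at a known intronic offset.

    Each exon is the middle of a three-exon gene on its own chromosome.
    Repressed exons get the motif planted in the upstream intron at
    ``offset_nt`` (negative, nt from the exon's 5' boundary to the
    motif start); activated exons get the mirrored downstream plant;
    background exons carry only chance motifs.
    """
    o = abs(int(offset_nt))
    if o + window > intron_len:
        raise ValueError(f"|offset| + window = {o + window} exceeds intron length {intron_len}")
    if o < len(motif):
        raise ValueError("offset must leave room for the motif inside the intron")
    rng = np.random.default_rng(seed)
    labels = ["activated"] * n_act + ["repressed"] * n_rep + ["background"] * n_bg

    rows = []
    annotation: list[AnnotationRecord] = []
    genome: dict[str, str] = {}
    truth = PlantedTruth(map_offsets={"activated": [], "repressed": [], "background": []})
    for i, label in enumerate(labels):
        chrom = f"chr_map{i:04d}"
        strand = str(rng.choice(["+", "-"]))
        e1 = (0, flank_exon_len)
        ce = (flank_exon_len + intron_len, flank_exon_len + intron_len + exon_len)
        e3_start = ce[1] + intron_len
        e3 = (e3_start, e3_start + flank_exon_len)
        seq = list(_rand_seq(rng, e3[1]))
        s, e = ce

        def _plant(sense_offset: int) -> None:
            """Write the motif so its sense-strand start sits at ``sense_offset``."""
            m = len(motif)
            if strand == "+":
                g0 = s + sense_offset if sense_offset < 0 else e + sense_offset
                seq[g0 : g0 + m] = list(motif)
            else:
                # mirror through the exon: sense-upstream is genomic right
                g0 = (e - sense_offset - m) if sense_offset < 0 else (s - sense_offset - m)
                seq[g0 : g0 + m] = list(reverse_complement(motif))

        if label == "repressed":
            _plant(-o)
            truth.map_offsets[label].append((chrom, -o))
        elif label == "activated":
            _plant(o)
            truth.map_offsets[label].append((chrom, o))

        genome[chrom] = "".join(seq)
        tx_id = f"{chrom}_t0"
        order = [e1, ce, e3] if strand == "+" else [e3, ce, e1]
        for rank, (xs, xe) in enumerate(order):
            annotation.append(
                AnnotationRecord(
                    chrom=chrom,
                    start=xs,
                    end=xe,
                    strand=strand,
                    gene_id=chrom,
                    transcript_id=tx_id,
                    exon_index=rank,
                )
            )
        rows.append(
            {
                "chrom": chrom,
                "start": s,
                "end": e,
                "strand": strand,
                "transcript_id": tx_id,
                "set": label,
            }
        )
    exon_sets = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "transcript_id", "set"])
    return exon_sets, annotation, genome, truth
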