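"""Four-(sub)genome benchmark generator with known truth.

The generator emulates the data structure behind a diploid-diploid-
allotetraploid trio: an ancestral gene set radiates into two diploid genomes
(Ar, Co) and, from those, the two subgenomes of an allotetraploid (An from
Ar, Cn from Co).  Every gene keeps a strict 1:1:1:1 correspondence and
collinear order, so tetrad identification has an exact truth.

Per tetrad the ancestral promoter (1.5 kb upstream + 0.5 kb downstream of
the TSS) carries implanted motif instances and, per epigenomic mark, an
optional peak footprint.  Mark-and-pair class labels drive the construction:

* Class I  - peak in both pair members, footprint sequence conserved;
* Class II - peak lost in the derived member, footprint sequence conserved;
* Class III- peak lost and footprint destroyed (footprint deletion, i.e. a
  structural variant, or dense substitutions plus a small indel);
* convergence implants force the An-Cn pair to be conserved at one layer
  while Ar-Co is divergent at it: epigenomic convergence removes Co's peak
  only, sequence convergence densely diverges the footprint on the Ar branch
  and copies the resulting An footprint sequence into Cn.

Background divergence (SNVs, small indels, occasional promoter deletions) is
applied on every branch of the lineage tree (ancestor -> lineage midpoint ->
{diploid, subgenome} siblings), with footprints shielded from
length-changing edits so truth labels survive; the A lineage's sibling
branches run at a higher rate than the C lineage's, mirroring the asymmetric
variability of the two subgenomes.  Expression is
lognormal around a shared tetrad baseline, multiplied up by activating marks
(H3K4me3, ACR), down by repressive ones (H3K27me3, H3K9me2), with pair
log-ratio noise growing with class (sigma_I < sigma_II < sigma_III).

With all rates at zero and class mix forced to Class I, the four genomes are
identical and the downstream pipeline must report 100% Class I, 100% "same",
conservation scores of 1 and zero variants.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .io_formats import (GENOME_LABELS, MARKS, CLASS_MARKS, GeneModel,
                         GenomeAssembly, Peak, write_bed_peaks,
                         write_expression_tsv, write_fasta, write_gff3)
from .liftover import reverse_complement

_BASES = np.array(list("ACGT"))

ACTIVATING_MARKS = ("H3K4me3", "ACR")
WEAK_ACTIVATING_MARKS = ("H3K4me1",)
REPRESSIVE_MARKS = ("H3K27me3", "H3K9me2")


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark (defaults are the
    package's reference scenario)."""

    n_tetrads: int = 2000
    seed: int = 42
    n_chroms: int = 2
    promoter_upstream: int = 1500
    promoter_downstream: int = 500
    gene_body_len: int = 600
    spacer_len: int = 300
    chrom_pad: int = 2000
    minus_strand_prob: float = 0.5
    # peaks and classes
    peak_prob: float = 0.7
    class_mix: dict = field(default_factory=lambda: {"I": 0.55, "II": 0.25, "III": 0.20})
    footprint_width_range: tuple = (120, 250)
    class3_sv_prob: float = 0.5
    dense_sub_rate: float = 0.4
    dense_indel_len_range: tuple = (10, 30)
    # background divergence per branch
    snv_rate: float = 0.02
    indel_rate: float = 0.001
    indel_len_range: tuple = (1, 10)
    sv_prob: float = 0.05
    sv_len_range: tuple = (60, 150)
    an_rate_factor: float = 1.5  # rate multiplier on the A lineage's sibling branches
    # convergence implants (per tetrad x mark with an ancestral peak)
    conv_epi_prob: float = 0.15
    conv_seq_prob: float = 0.10
    # motifs
    motif_implant_prob: float = 0.25
    motif_noise: float = 0.1
    # per-instance, per-leaf-branch TFBS turnover (disruption of an implanted
    # instance by a small core deletion or dense substitution); the A
    # lineage's branches scale by an_rate_factor
    motif_disruption_prob: float = 0.25
    # per-gene, per-lineage lognormal mutation-rate heterogeneity (sigma of
    # the log rate modifier; 0 = homogeneous rates).  Hot promoters
    # accumulate both more variants and more TFBS turnover, coupling variant
    # burden to conservation-score loss.
    rate_heterogeneity_sigma: float = 0.6
    # expression
    expression_base_log2: float = 4.0
    expression_base_sigma: float = 1.2
    mark_effect: float = 2.0
    baseline_sigma: float = 0.3
    expression_sigma: dict = field(default_factory=lambda: {"I": 0.25, "II": 0.5, "III": 1.0})

    def __post_init__(self):
        if self.n_tetrads < 1:
            raise ValueError("n_tetrads must be >= 1")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        for rate in (self.snv_rate, self.indel_rate, self.sv_prob,
                     self.conv_epi_prob, self.conv_seq_prob,
                     self.motif_implant_prob, self.motif_noise,
                     self.motif_disruption_prob, self.peak_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rates must lie in [0,1], got {rate}")

    @property
    def promoter_len(self) -> int:
        return self.promoter_upstream + self.promoter_downstream

    @classmethod
    def zero_noise(cls, n_tetrads: int = 100, seed: int = 42, **kw) -> "SimConfig":
        """All divergence off: four identical genomes, all peaks Class I."""
        return cls(n_tetrads=n_tetrads, seed=seed,
                   class_mix={"I": 1.0, "II": 0.0, "III": 0.0},
                   snv_rate=0.0, indel_rate=0.0, sv_prob=0.0,
                   conv_epi_prob=0.0, conv_seq_prob=0.0, motif_noise=0.0,
                   motif_disruption_prob=0.0,
                   expression_sigma={"I": 0.0, "II": 0.0, "III": 0.0},
                   baseline_sigma=0.0, expression_base_sigma=0.0, **kw)


def _rng(cfg: SimConfig, stage: str) -> np.random.Generator:
    """Stage-keyed substream of the run seed (stage independence without
    cross-talk)."""
    digest = sum(ord(c) * 131 ** i for i, c in enumerate(stage)) % (2 ** 31)
    return np.random.default_rng([cfg.seed % (2 ** 31), digest])


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# edit machinery

@dataclass
class Edit:
    kind: str  # 'sub' | 'del' | 'ins'
    pos: int   # parent coordinate (insertions go before this position)
    length: int
    payload: str = ""  # new base(s) for sub/ins

    @property
    def span(self) -> tuple[int, int]:
        """Occupied parent interval (insertions occupy a zero-width point)."""
        if self.kind == "ins":
            return (self.pos, self.pos)
        return (self.pos, self.pos + self.length)


def apply_edits(seq: str, edits: list[Edit]) -> tuple[str, np.ndarray]:
    """Apply non-overlapping edits; return the child sequence and a boundary
    map ``m`` of length len(seq)+1 with ``m[i]`` = child coordinate of parent
    boundary ``i`` (so a parent interval [s,e) maps to [m[s], m[e]))."""
    n = len(seq)
    edits = sorted(edits, key=lambda e: (e.pos, e.kind != "ins"))
    out: list[str] = []
    m = np.empty(n + 1, dtype=np.int64)
    cursor = 0
    child = 0
    for e in edits:
        if e.pos < cursor:
            raise ValueError("overlapping edits")
        seg = seq[cursor:e.pos]
        out.append(seg)
        m[cursor:e.pos] = child + np.arange(len(seg))
        child += len(seg)
        cursor = e.pos
        if e.kind == "sub":
            out.append(e.payload)
            m[cursor:cursor + e.length] = child + np.arange(e.length)
            child += e.length
            cursor += e.length
        elif e.kind == "del":
            m[cursor:cursor + e.length] = child
            cursor += e.length
        elif e.kind == "ins":
            out.append(e.payload)
            child += len(e.payload)
        else:
            raise ValueError(f"unknown edit kind {e.kind!r}")
    seg = seq[cursor:]
    out.append(seg)
    m[cursor:n] = child + np.arange(len(seg))
    m[n] = child + len(seg)
    return "".join(out), m


def _overlaps(span: tuple[int, int], intervals: list[tuple[int, int]]) -> bool:
    s, e = span
    if e == s:
        e = s + 1
    return any(s < ie and is_ < e for is_, ie in intervals)


def sample_background_edits(rng: np.random.Generator, seq: str,
                            snv_rate: float, indel_rate: float,
                            indel_len_range: tuple, sv_prob: float,
                            sv_len_range: tuple,
                            protected: list[tuple[int, int]]) -> list[Edit]:
    """Background divergence for one branch: SNVs anywhere (dedup by
    position), small insertions/deletions and an occasional larger deletion
    outside the ``protected`` intervals."""
    n = len(seq)
    edits: list[Edit] = []
    occupied: list[tuple[int, int]] = []

    def try_add(e: Edit, avoid_protected: bool) -> bool:
        if e.span[1] > n:
            return False
        if _overlaps(e.span, occupied):
            return False
        if avoid_protected and _overlaps(e.span, protected):
            return False
        edits.append(e)
        occupied.append(e.span if e.span[1] > e.span[0] else (e.pos, e.pos + 1))
        return True

    if sv_prob > 0 and rng.random() < sv_prob:
        length = int(rng.integers(sv_len_range[0], sv_len_range[1] + 1))
        for _ in range(20):  # retry placement around protected regions
            pos = int(rng.integers(0, max(1, n - length)))
            if try_add(Edit("del", pos, length), avoid_protected=True):
                break
    if indel_rate > 0:
        n_indels = rng.binomial(n, indel_rate)
        for _ in range(n_indels):
            length = int(rng.integers(indel_len_range[0], indel_len_range[1] + 1))
            pos = int(rng.integers(0, max(1, n - length)))
            if rng.random() < 0.5:
                try_add(Edit("del", pos, length), avoid_protected=True)
            else:
                try_add(Edit("ins", pos, length, random_dna(rng, length)),
                        avoid_protected=True)
    if snv_rate > 0:
        for pos in np.nonzero(rng.random(n) < snv_rate)[0]:
            pos = int(pos)
            old = seq[pos]
            if old not in "ACGT":
                continue
            choices = [b for b in "ACGT" if b != old]
            new = choices[rng.integers(0, 3)]
            try_add(Edit("sub", pos, 1, new), avoid_protected=False)
    return edits


def dense_divergence_edits(rng: np.random.Generator, seq: str,
                           footprint: tuple[int, int], sub_rate: float,
                           indel_len_range: tuple | None) -> list[Edit]:
    """Destroy a footprint's sequence identity: substitutions at ``sub_rate``
    plus, optionally, one small deletion inside the footprint."""
    s, e = footprint
    edits: list[Edit] = []
    for pos in np.nonzero(rng.random(e - s) < sub_rate)[0]:
        pos = int(pos) + s
        old = seq[pos]
        if old not in "ACGT":
            continue
        choices = [b for b in "ACGT" if b != old]
        edits.append(Edit("sub", pos, 1, choices[rng.integers(0, 3)]))
    if indel_len_range is not None:
        length = int(rng.integers(indel_len_range[0], indel_len_range[1] + 1))
        width = e - s
        if width > length + 2:
            pos = s + int(rng.integers(1, width - length - 1))
            edits = [ed for ed in edits if not _overlaps(ed.span, [(pos, pos + length)])]
            edits.append(Edit("del", pos, length))
    return edits


# ---------------------------------------------------------------------------
# ancestral gene set

@dataclass
class AncestralGene:
    tetrad_id: str
    chrom: str
    order: int
    strand: str
    promoter: str                       # transcription direction, len = promoter_len
    footprints: dict                    # mark -> (start, end) or None
    motif_implants: list                # (motif_id, offset)
    spacer: str
    body_tail: str


def _load_packaged_motifs():
    from .tfbs import read_jaspar
    ref = importlib.resources.files("homeoconverge.data") / "plant_motifs_synthetic.jaspar"
    with importlib.resources.as_file(ref) as path:
        return read_jaspar(path)


def simulate_ancestor(cfg: SimConfig) -> list[AncestralGene]:
    """Ancestral gene set: i.i.d. uniform promoters with implanted motif
    instances and disjoint per-mark peak-footprint slots."""
    rng = _rng(cfg, "ancestor")
    pwms = _load_packaged_motifs()
    plen = cfg.promoter_len
    n_marks = len(MARKS)
    # disjoint slots for footprints, kept >=450 bases from the far upstream
    # edge so deletions can never push a footprint out of the extraction window
    slot_lo, slot_hi = 450, plen - 100
    slot_w = (slot_hi - slot_lo) // n_marks
    if slot_w <= cfg.footprint_width_range[1] + 10:
        raise ValueError("promoter too short for disjoint footprint slots")
    genes: list[AncestralGene] = []
    per_chrom = int(np.ceil(cfg.n_tetrads / cfg.n_chroms))
    for t in range(cfg.n_tetrads):
        tid = f"g{t + 1:05d}"
        chrom = f"chr{t // per_chrom + 1}"
        order = t % per_chrom
        strand = "-" if rng.random() < cfg.minus_strand_prob else "+"
        promoter = list(random_dna(rng, plen))
        implants = []
        for pwm in pwms:
            if rng.random() < cfg.motif_implant_prob:
                inst = list(pwm.consensus)
                for k in range(len(inst)):
                    if rng.random() < cfg.motif_noise:
                        inst[k] = "ACGT"[rng.integers(0, 4)]
                off = int(rng.integers(0, plen - len(inst)))
                promoter[off:off + len(inst)] = inst
                implants.append((pwm.motif_id, off))
        footprints: dict = {}
        slots = rng.permutation(n_marks)
        for mark, slot in zip(MARKS, slots):
            width = int(rng.integers(*cfg.footprint_width_range))
            lo = slot_lo + slot * slot_w
            start = lo + int(rng.integers(0, slot_w - width))
            footprints[mark] = (start, start + width)
        genes.append(AncestralGene(
            tetrad_id=tid, chrom=chrom, order=order, strand=strand,
            promoter="".join(promoter), footprints=footprints,
            motif_implants=implants,
            spacer=random_dna(rng, cfg.spacer_len),
            body_tail=random_dna(rng, max(0, cfg.gene_body_len - cfg.promoter_downstream))))
    return genes


# ---------------------------------------------------------------------------
# truth-driven derivation of the four genomes

@dataclass
class TetradTruth:
    tetrad_id: str
    mode_by_mark: dict      # mark -> 'none' | 'normal' | 'conv_epi' | 'conv_seq'
    class_ar_an: dict       # mark -> 'I'|'II'|'III'|'no_peak'
    class_co_cn: dict
    peak_presence: dict     # mark -> {genome: bool}


@dataclass
class SimulatedDataset:
    cfg: SimConfig
    assemblies: dict        # label -> GenomeAssembly
    genes: dict             # label -> list[GeneModel] (tetrad order)
    peaks: dict             # label -> list[Peak]
    expression: dict        # label -> {gene_id: tpm}
    truth: list             # list[TetradTruth]
    tetrad_gene_ids: dict   # tetrad_id -> {label: gene_id}
    peak_scores: dict       # (label, gene_id, mark) -> score

    def truth_frame(self):
        import pandas as pd
        rows = []
        for t in self.truth:
            for mark in MARKS:
                rows.append({
                    "tetrad_id": t.tetrad_id, "mark": mark,
                    "mode": t.mode_by_mark[mark],
                    "class_Ar-An": t.class_ar_an[mark],
                    "class_Co-Cn": t.class_co_cn[mark],
                    **{f"peak_{g}": int(t.peak_presence[mark][g])
                       for g in GENOME_LABELS}})
        return pd.DataFrame(rows)


def _draw_class(rng: np.random.Generator, mix: dict) -> str:
    u = rng.random()
    acc = 0.0
    for klass in ("I", "II", "III"):
        acc += mix.get(klass, 0.0)
        if u < acc:
            return klass
    return "III"


def derive_four_genomes(ancestor: list[AncestralGene],
                        cfg: SimConfig) -> SimulatedDataset:
    """Build Ar/Co/An/Cn genomes, annotations, peaks and truth labels."""
    rng = _rng(cfg, "derive")
    plen = cfg.promoter_len
    pwm_len = {p.motif_id: p.length for p in _load_packaged_motifs()}

    chrom_seqs = {g: {} for g in GENOME_LABELS}
    gene_models = {g: [] for g in GENOME_LABELS}
    peaks = {g: [] for g in GENOME_LABELS}
    truth: list[TetradTruth] = []
    tetrad_gene_ids: dict = {}
    peak_scores: dict = {}
    chrom_parts = {g: {} for g in GENOME_LABELS}  # label -> chrom -> [segments]
    chrom_cursor = {g: {} for g in GENOME_LABELS}

    for anc in ancestor:
        all_fps = [fp for fp in anc.footprints.values() if fp is not None]

        # -- truth decisions -------------------------------------------------
        has_peak = {m: rng.random() < cfg.peak_prob for m in MARKS}
        mode: dict = {}
        cls_ar_an: dict = {}
        cls_co_cn: dict = {}
        presence: dict = {m: dict.fromkeys(GENOME_LABELS, False) for m in MARKS}
        for m in MARKS:
            if not has_peak[m]:
                mode[m] = "none"
                cls_ar_an[m] = cls_co_cn[m] = "no_peak"
                continue
            u = rng.random()
            if u < cfg.conv_epi_prob:
                mode[m] = "conv_epi"
                cls_ar_an[m] = "I"
                cls_co_cn[m] = "II"
                presence[m] = {"Ar": True, "Co": False, "An": True, "Cn": True}
            elif u < cfg.conv_epi_prob + cfg.conv_seq_prob:
                mode[m] = "conv_seq"
                cls_ar_an[m] = "I"
                cls_co_cn[m] = "III"
                presence[m] = {"Ar": True, "Co": False, "An": True, "Cn": True}
            else:
                mode[m] = "normal"
                ka = _draw_class(rng, cfg.class_mix)
                kc = _draw_class(rng, cfg.class_mix)
                cls_ar_an[m] = ka
                cls_co_cn[m] = kc
                presence[m] = {"Ar": True, "Co": True,
                               "An": ka == "I", "Cn": kc == "I"}

        # -- sequence derivation along the two lineages ----------------------
        # Each lineage has a shared midpoint (the common ancestor of the
        # extant diploid and the subgenome, which are siblings, not
        # parent/child): anc -> midA -> {Ar, An} and anc -> midC -> {Co, Cn}.
        # conv_seq dense divergence sits on the midA step so Ar and An share
        # it; class-III destruction sits on the subgenome branches.  The A
        # lineage's sibling branches run at an elevated rate, making Ar-An
        # carry more variants and An a lower TFBS conservation than Cn.
        anc_tss = (cfg.promoter_upstream if anc.strand == "+"
                   else cfg.promoter_upstream - 1)
        # rate modifiers: lineage asymmetry x per-gene heterogeneity (capped
        # so shielded-footprint identity stays clear of the class thresholds)
        sig = cfg.rate_heterogeneity_sigma
        h_a = min(float(rng.lognormal(0.0, sig)), 4.0) if sig > 0 else 1.0
        h_c = min(float(rng.lognormal(0.0, sig)), 4.0) if sig > 0 else 1.0
        f_a = cfg.an_rate_factor * h_a
        f_c = h_c

        mid_explicit: list[Edit] = []
        for m in MARKS:
            if mode[m] == "conv_seq":
                mid_explicit += dense_divergence_edits(
                    rng, anc.promoter, anc.footprints[m],
                    cfg.dense_sub_rate, None)
        mid_a_edits = _dedupe(mid_explicit + sample_background_edits(
            rng, anc.promoter, cfg.snv_rate, cfg.indel_rate,
            cfg.indel_len_range, cfg.sv_prob, cfg.sv_len_range,
            protected=all_fps))
        seq_mid_a, map_mid_a = apply_edits(anc.promoter, mid_a_edits)
        fp_mid_a = {m: (int(map_mid_a[s]), int(map_mid_a[e]))
                    for m, (s, e) in anc.footprints.items()}
        tss_mid_a = int(map_mid_a[anc_tss])

        mid_c_edits = sample_background_edits(
            rng, anc.promoter, cfg.snv_rate, cfg.indel_rate,
            cfg.indel_len_range, cfg.sv_prob, cfg.sv_len_range,
            protected=all_fps)
        seq_mid_c, map_mid_c = apply_edits(anc.promoter, mid_c_edits)
        fp_mid_c = {m: (int(map_mid_c[s]), int(map_mid_c[e]))
                    for m, (s, e) in anc.footprints.items()}
        tss_mid_c = int(map_mid_c[anc_tss])

        def remap_implants(mp):
            out = []
            for motif_id, off in anc.motif_implants:
                length = pwm_len[motif_id]
                s, e = int(mp[off]), int(mp[off + length])
                if e - s == length:  # instance intact after the mid step
                    out.append((s, e))
            return out

        implants_mid = {"A": remap_implants(map_mid_a),
                        "C": remap_implants(map_mid_c)}

        def derive_leaf(seq_mid, fp_mid, tss_mid, rate, destroyed_marks,
                        implants):
            explicit: list[Edit] = []
            for m in destroyed_marks:
                s, e = fp_mid[m]
                if rng.random() < cfg.class3_sv_prob and (e - s) > 50:
                    explicit.append(Edit("del", s, e - s))
                else:
                    explicit += dense_divergence_edits(
                        rng, seq_mid, (s, e), cfg.dense_sub_rate,
                        cfg.dense_indel_len_range)
            # TFBS turnover: disrupt implanted instances outside footprints
            fps = list(fp_mid.values())
            p_disrupt = min(1.0, cfg.motif_disruption_prob * rate)
            for s, e in implants:
                if _overlaps((s, e), fps) or rng.random() >= p_disrupt:
                    continue
                if rng.random() < 0.5 and (e - s) > 12:
                    d = int(rng.integers(4, 11))
                    explicit.append(Edit("del", s + (e - s - d) // 2, d))
                else:
                    explicit += dense_divergence_edits(
                        rng, seq_mid, (s, e), 0.5, None)
            edits = _dedupe(explicit + sample_background_edits(
                rng, seq_mid, cfg.snv_rate * rate, cfg.indel_rate * rate,
                cfg.indel_len_range, min(1.0, cfg.sv_prob * rate),
                cfg.sv_len_range, protected=list(fp_mid.values())))
            seq, mp = apply_edits(seq_mid, edits)
            fp = {m: (int(mp[s]), int(mp[e])) for m, (s, e) in fp_mid.items()}
            return seq, fp, int(mp[tss_mid])

        destroyed_an = [m for m in MARKS
                        if mode[m] == "normal" and cls_ar_an[m] == "III"]
        destroyed_cn = [m for m in MARKS
                        if mode[m] == "normal" and cls_co_cn[m] == "III"]
        seq_ar, fp_ar, tss_ar = derive_leaf(seq_mid_a, fp_mid_a, tss_mid_a,
                                            f_a, [], implants_mid["A"])
        seq_an, fp_an, tss_an = derive_leaf(seq_mid_a, fp_mid_a, tss_mid_a,
                                            f_a, destroyed_an, implants_mid["A"])
        seq_co, fp_co, tss_co = derive_leaf(seq_mid_c, fp_mid_c, tss_mid_c,
                                            f_c, [], implants_mid["C"])
        seq_cn, fp_cn, tss_cn = derive_leaf(seq_mid_c, fp_mid_c, tss_mid_c,
                                            f_c, destroyed_cn, implants_mid["C"])
        tss_off = {"Ar": tss_ar, "Co": tss_co, "An": tss_an, "Cn": tss_cn}

        # sequence convergence: copy the An footprint sequence into Cn so the
        # subgenomes match while Ar-Co stays divergent
        for m in MARKS:
            if mode[m] == "conv_seq":
                sa, ea = fp_an[m]
                sc, ec = fp_cn[m]
                new_len = ea - sa
                seq_cn = seq_cn[:sc] + seq_an[sa:ea] + seq_cn[ec:]
                fp_cn = _shift_footprints(fp_cn, m, sc, ec, new_len)
                if tss_off["Cn"] >= ec:
                    tss_off["Cn"] += new_len - (ec - sc)
                elif tss_off["Cn"] > sc:
                    tss_off["Cn"] = min(sc + (tss_off["Cn"] - sc), sc + new_len)
        sequences = {"Ar": seq_ar, "Co": seq_co, "An": seq_an, "Cn": seq_cn}
        footprints = {"Ar": fp_ar, "Co": fp_co, "An": fp_an, "Cn": fp_cn}

        # -- placement on chromosomes ---------------------------------------
        tetrad_gene_ids[anc.tetrad_id] = {}
        for g in GENOME_LABELS:
            gene_id = f"{anc.tetrad_id}_{g}"
            tetrad_gene_ids[anc.tetrad_id][g] = gene_id
            seq = sequences[g]
            lg = len(seq)
            parts = chrom_parts[g].setdefault(anc.chrom, [])
            cursor = chrom_cursor[g].setdefault(anc.chrom, 0)
            if not parts:
                parts.append(random_dna(rng, cfg.chrom_pad))
                cursor = cfg.chrom_pad
            parts.append(anc.spacer)
            cursor += len(anc.spacer)
            seg_start = cursor
            if anc.strand == "+":
                parts.append(seq)
                parts.append(anc.body_tail)
                tss = seg_start + tss_off[g]
                span = (tss, min(tss + cfg.gene_body_len,
                                 seg_start + lg + len(anc.body_tail)))
                for m in MARKS:
                    if presence[m][g]:
                        s, e = footprints[g][m]
                        _add_peak(peaks, peak_scores, rng, g, anc.chrom,
                                  seg_start + s, seg_start + e, m, gene_id)
            else:
                parts.append(anc.body_tail)
                seg_start = cursor + len(anc.body_tail)
                parts.append(reverse_complement(seq))
                tss = seg_start + lg - 1 - tss_off[g]
                span = (max(seg_start - len(anc.body_tail),
                            tss - cfg.gene_body_len + 1), tss + 1)
                for m in MARKS:
                    if presence[m][g]:
                        s, e = footprints[g][m]
                        _add_peak(peaks, peak_scores, rng, g, anc.chrom,
                                  seg_start + lg - e, seg_start + lg - s, m, gene_id)
            cursor = seg_start + lg if anc.strand == "-" else seg_start + lg + len(anc.body_tail)
            chrom_cursor[g][anc.chrom] = cursor
            gene_models[g].append(GeneModel(
                gene_id=gene_id, chrom=anc.chrom, strand=anc.strand,
                tss=tss, span=span))

        truth.append(TetradTruth(
            tetrad_id=anc.tetrad_id, mode_by_mark=mode,
            class_ar_an=cls_ar_an, class_co_cn=cls_co_cn,
            peak_presence=presence))

    assemblies = {}
    for g in GENOME_LABELS:
        seqs = {}
        for c in sorted(chrom_parts[g]):
            # trailing pad so the last gene's promoter window never clips
            chrom_parts[g][c].append(random_dna(rng, cfg.chrom_pad))
            seqs[c] = "".join(chrom_parts[g][c])
        assemblies[g] = GenomeAssembly(label=g, sequences=seqs)

    ds = SimulatedDataset(cfg=cfg, assemblies=assemblies, genes=gene_models,
                          peaks=peaks, expression={}, truth=truth,
                          tetrad_gene_ids=tetrad_gene_ids,
                          peak_scores=peak_scores)
    ds.expression = simulate_expression(ds, cfg)
    return ds


def _dedupe(edits: list[Edit]) -> list[Edit]:
    """Drop later edits that overlap earlier ones (explicit edits first)."""
    kept: list[Edit] = []
    occupied: list[tuple[int, int]] = []
    for e in edits:
        span = e.span if e.span[1] > e.span[0] else (e.pos, e.pos + 1)
        if _overlaps(span, occupied):
            continue
        kept.append(e)
        occupied.append(span)
    return kept


def _shift_footprints(fps: dict, edited_mark: str, s: int, e: int,
                      new_len: int) -> dict:
    """Adjust footprint coordinates after splicing ``new_len`` bases over
    [s, e) (the edited mark's footprint becomes the spliced interval)."""
    delta = new_len - (e - s)
    out = {}
    for m, (fs, fe) in fps.items():
        if m == edited_mark:
            out[m] = (s, s + new_len)
        elif fs >= e:
            out[m] = (fs + delta, fe + delta)
        else:
            out[m] = (fs, fe)
    return out


def _add_peak(peaks, peak_scores, rng, g, chrom, start, end, mark, gene_id):
    score = float(np.round(rng.lognormal(np.log(10), 0.5), 3))
    peaks[g].append(Peak(chrom=chrom, start=start, end=end, mark=mark, score=score))
    peak_scores[(g, gene_id, mark)] = score


def simulate_expression(ds: SimulatedDataset, cfg: SimConfig) -> dict:
    """Per-genome TPM tables coupled to peak presence and class labels."""
    rng = _rng(cfg, "expression")
    up = np.log2(cfg.mark_effect) if cfg.mark_effect > 0 else 0.0
    order = {"no_peak": 0, "I": 1, "II": 2, "III": 3}
    sigma_of = {"I": cfg.expression_sigma["I"], "II": cfg.expression_sigma["II"],
                "III": cfg.expression_sigma["III"], "no_peak": cfg.baseline_sigma}
    expr = {g: {} for g in GENOME_LABELS}
    for t in ds.truth:
        base = cfg.expression_base_log2 + rng.normal(0.0, cfg.expression_base_sigma)
        worst_an = max((t.class_ar_an[m] for m in CLASS_MARKS
                        if t.class_ar_an[m] != "no_peak"),
                       key=lambda k: order[k], default="no_peak")
        worst_cn = max((t.class_co_cn[m] for m in CLASS_MARKS
                        if t.class_co_cn[m] != "no_peak"),
                       key=lambda k: order[k], default="no_peak")
        noise_sigma = {"Ar": cfg.baseline_sigma, "Co": cfg.baseline_sigma,
                       "An": sigma_of[worst_an], "Cn": sigma_of[worst_cn]}
        for g in GENOME_LABELS:
            l2 = base + rng.normal(0.0, noise_sigma[g])
            for m in MARKS:
                if not t.peak_presence[m][g]:
                    continue
                if m in ACTIVATING_MARKS:
                    l2 += up
                elif m in WEAK_ACTIVATING_MARKS:
                    l2 += 0.5 * up
                else:
                    l2 -= up
            gene_id = ds.tetrad_gene_ids[t.tetrad_id][g]
            expr[g][gene_id] = float(np.round(2.0 ** l2, 4))
    return expr


# ---------------------------------------------------------------------------
# file emission

def simulate(cfg: SimConfig) -> SimulatedDataset:
    """Run the full generator (ancestor + derivation + expression)."""
    return derive_four_genomes(simulate_ancestor(cfg), cfg)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> Path:
    """Emit the dataset in the exact formats the pipeline reads, plus truth
    tables, and return the directory."""
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "expression").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    for g in GENOME_LABELS:
        write_fasta(outdir / f"{g}.fa", ds.assemblies[g].sequences)
        write_gff3(outdir / f"{g}.gff3", ds.genes[g])
        for mark in MARKS:
            write_bed_peaks(outdir / "peaks" / f"{g}_{mark}.bed",
                            [p for p in ds.peaks[g] if p.mark == mark])
        write_expression_tsv(outdir / "expression" / f"{g}.tsv", ds.expression[g])
    ref = importlib.resources.files("homeoconverge.data") / "plant_motifs_synthetic.jaspar"
    (outdir / "motifs.jaspar").write_text(ref.read_text())

    import pandas as pd
    ds.truth_frame().to_csv(outdir / "truth" / "classes.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"tetrad_id": tid, **genes}
        for tid, genes in sorted(ds.tetrad_gene_ids.items())
    ]).to_csv(outdir / "truth" / "tetrads.tsv", sep="\t", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(ds.cfg), fh, sort_keys=True)
    return outdir
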