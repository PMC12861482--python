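"""End-to-end orchestration: tetrads -> promoter alignment -> conservation
classes -> convergence -> expression statistics -> TFBS -> variants.

The pipeline consumes a :class:`DataBundle` (four genome assemblies with gene
models, per-mark peak sets, TPM tables and a motif library), which can come
from the synthetic generator in memory or from files on disk, and produces
per-call tables plus the summary statistics of a run.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import convergence as conv
from . import peak_conservation as pc
from .expression import log2_fold_change, signal_expression_correlation
from .io_formats import (CLASS_MARKS, GENOME_LABELS, MARKS, log,
                         read_bed_peaks, read_expression_tsv, read_fasta,
                         read_gff3, sha256_file, write_results)
from .liftover import align_promoters, extract_promoter
from .tetrads import (GeneSeq, Tetrad, assemble_tetrads, best_hits,
                      collinear_chains)
from .tfbs import (high_conservation_fraction, read_jaspar,
                   scan_promoter_all, target_count_comparison,
                   tf_target_counts, tfbs_conservation_score)
from .variants import call_variants, overlap_with_tfbs, variation_length_vs_cs

#: the two diploid-vs-tetraploid axes and the two within-ploidy axes
PAIR_MEMBERS = {"Ar-An": ("Ar", "An"), "Co-Cn": ("Co", "Cn"),
                "Ar-Co": ("Ar", "Co"), "An-Cn": ("An", "Cn")}


@dataclass
class Thresholds:
    """All analysis thresholds in one place, with the package's documented
    defaults (see docs/methods.md for the rationale behind each)."""

    min_lift: float = 0.5
    min_identity: float = 0.7
    min_peak_overlap: float = 0.5
    motif_score: float = 10.0
    fc_threshold: float = 1.0
    cs_cutoff: float = 0.6
    cscore: float = 0.99
    min_anchors: int = 4
    max_gap: int = 10


@dataclass
class DataBundle:
    assemblies: dict
    genes: dict                  # label -> list[GeneModel]
    peaks: dict                  # label -> list[Peak]
    expression: dict             # label -> {gene_id: tpm}
    pwms: list

    @classmethod
    def from_simulated(cls, ds) -> "DataBundle":
        from .synthetic_data import _load_packaged_motifs
        return cls(assemblies=ds.assemblies, genes=ds.genes, peaks=ds.peaks,
                   expression=ds.expression, pwms=_load_packaged_motifs())

    @classmethod
    def from_dir(cls, path: str | Path) -> "DataBundle":
        """Load a dataset directory as written by the generator
        (``<label>.fa``, ``<label>.gff3``, ``peaks/<label>_<mark>.bed``,
        ``expression/<label>.tsv``, ``motifs.jaspar``)."""
        path = Path(path)
        assemblies, genes, peaks, expression = {}, {}, {}, {}
        for g in GENOME_LABELS:
            assemblies[g] = read_fasta(path / f"{g}.fa", label=g)
            genes[g] = read_gff3(path / f"{g}.gff3", assemblies[g])
            peaks[g] = []
            for mark in MARKS:
                bed = path / "peaks" / f"{g}_{mark}.bed"
                if not bed.exists():
                    raise FileNotFoundError(
                        f"missing peak file for mark {mark!r}: {bed}")
                peaks[g].extend(read_bed_peaks(bed, mark))
            expression[g] = read_expression_tsv(path / "expression" / f"{g}.tsv")
        return cls(assemblies=assemblies, genes=genes, peaks=peaks,
                   expression=expression, pwms=read_jaspar(path / "motifs.jaspar"))


@dataclass
class PipelineResult:
    tetrads: list
    pair_calls: list             # list[PairCall]
    convergence_calls: list      # list[ConvergenceCall]
    expression_convergence: dict  # tetrad_id -> bool
    divergence: pd.DataFrame     # per tetrad x pair log2fc + tpm diff
    cs_scores: dict              # 'An'/'Cn' -> list[ConservationScore]
    variants: dict               # (tetrad_id, pair) -> list[VariantRecord]
    motif_hits: dict             # label -> {gene_id: list[MotifHit]}
    summary: dict

    def tables(self) -> dict:
        """Result tables for :func:`homeoconverge.io_formats.write_results`."""
        calls = pd.DataFrame([{
            "tetrad_id": c.tetrad_id, "pair": c.pair, "mark": c.mark,
            "seq_conserved": int(c.seq_conserved),
            "epi_conserved": int(c.epi_conserved), "class": c.klass,
        } for c in self.pair_calls])
        convs = pd.DataFrame([{
            "tetrad_id": c.tetrad_id, "mark": c.mark, "layer": c.layer,
            "category": c.category,
        } for c in self.convergence_calls])
        tets = pd.DataFrame([{"tetrad_id": t.tetrad_id, **t.genes}
                             for t in self.tetrads])
        var_rows = []
        for (tid, pair), vs in self.variants.items():
            for v in vs:
                var_rows.append({
                    "tetrad_id": tid, "pair": pair, "vtype": v.vtype,
                    "position": v.position, "length": v.length,
                    "overlaps_nonconserved_tfbs": int(v.overlaps_nonconserved_tfbs)})
        cs_rows = [{"gene_id": s.gene_id, "subgenome": sub,
                    "n_total": s.n_total, "n_conserved": s.n_conserved,
                    "cs": "" if s.cs is None else round(s.cs, 4)}
                   for sub, scores in self.cs_scores.items() for s in scores]
        return {
            "tetrads": tets,
            "pair_calls": calls,
            "convergence_calls": convs,
            "expression_divergence": self.divergence,
            "variants": pd.DataFrame(var_rows),
            "tfbs_conservation": pd.DataFrame(cs_rows),
        }


def identify_tetrads(bundle: DataBundle, promoters: dict,
                     thresholds: Thresholds) -> list[Tetrad]:
    """RBH + collinearity + cscore filtering over the four promoter sets."""
    gene_seqs, orders = {}, {}
    for g in GENOME_LABELS:
        per_chrom: dict[str, int] = {}
        seqs = []
        order = {}
        for gene in sorted(bundle.genes[g], key=lambda x: (x.chrom, x.tss)):
            rank = per_chrom.get(gene.chrom, 0)
            per_chrom[gene.chrom] = rank + 1
            seqs.append(GeneSeq(gene_id=gene.gene_id, chrom=gene.chrom,
                                rank=rank,
                                sequence=promoters[g][gene.gene_id].sequence))
            order[gene.gene_id] = (gene.chrom, rank)
        gene_seqs[g], orders[g] = seqs, order

    def syntenic(a: str, b: str):
        pairs = best_hits(gene_seqs[a], gene_seqs[b])
        return collinear_chains(pairs, orders[a], orders[b],
                                min_anchors=thresholds.min_anchors,
                                max_gap=thresholds.max_gap,
                                cscore_threshold=thresholds.cscore)

    ar_co = syntenic("Ar", "Co")
    ar_an = syntenic("Ar", "An")
    co_cn = syntenic("Co", "Cn")
    an_cn = syntenic("An", "Cn")
    return assemble_tetrads(ar_co, ar_an, co_cn, an_cn)


def peaks_in_promoters(bundle: DataBundle, promoters: dict) -> dict:
    """label -> gene_id -> mark -> list of promoter-coordinate intervals."""
    out: dict = {}
    for g in GENOME_LABELS:
        trees: dict[str, IntervalTree] = {}
        for gene_id, prom in promoters[g].items():
            s, e = prom.interval
            trees.setdefault(prom.chrom, IntervalTree()).addi(s, e, gene_id)
        gmap: dict = {gene_id: {m: [] for m in MARKS}
                      for gene_id in promoters[g]}
        for peak in bundle.peaks[g]:
            tree = trees.get(peak.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(peak.start, peak.end):
                prom = promoters[g][iv.data]
                cs, ce = max(peak.start, iv.begin), min(peak.end, iv.end)
                ps, pe = prom.to_promoter_coords(cs, ce)
                gmap[iv.data][peak.mark].append((ps, pe))
        for per_gene in gmap.values():
            for m in MARKS:
                per_gene[m].sort()
        out[g] = gmap
    return out


def run_pipeline(bundle: DataBundle, thresholds: Thresholds | None = None,
                 tetrads: list | None = None) -> PipelineResult:
    """Run every analysis stage; pass ``tetrads`` to skip identification
    (e.g. to use known truth quartets)."""
    th = thresholds or Thresholds()
    t0 = time.time()
    promoters = {g: {gene.gene_id: extract_promoter(gene, bundle.assemblies[g])
                     for gene in bundle.genes[g]}
                 for g in GENOME_LABELS}
    if tetrads is None:
        tetrads = identify_tetrads(bundle, promoters, th)
        log.info("identified %d tetrads (%.1fs)", len(tetrads), time.time() - t0)
    peak_map = peaks_in_promoters(bundle, promoters)

    # promoter alignments per tetrad and pair axis
    alignments: dict = {}
    pair_calls: list = []
    for tet in tetrads:
        for pair, (ga, gb) in PAIR_MEMBERS.items():
            ida, idb = tet.genes[ga], tet.genes[gb]
            aln = align_promoters(promoters[ga][ida].sequence,
                                  promoters[gb][idb].sequence,
                                  gene_a=ida, gene_b=idb)
            alignments[(tet.tetrad_id, pair)] = aln
            for mark in MARKS:
                pair_calls.append(pc.call_peak_conservation(
                    tet.tetrad_id, pair, mark,
                    peak_map[ga][ida][mark], peak_map[gb][idb][mark], aln,
                    min_lift=th.min_lift, min_identity=th.min_identity,
                    min_peak_overlap=th.min_peak_overlap))
    log.info("aligned and classified %d tetrads (%.1fs)", len(tetrads),
             time.time() - t0)

    # convergence per mark
    convergence_calls: list = []
    by_pair_mark: dict = {}
    for c in pair_calls:
        by_pair_mark.setdefault((c.pair, c.mark), {})[c.tetrad_id] = c
    for mark in MARKS:
        an_cn = by_pair_mark.get(("An-Cn", mark), {})
        ar_co = by_pair_mark.get(("Ar-Co", mark), {})
        convergence_calls += conv.call_epigenomic_convergence(an_cn, ar_co, mark)
        convergence_calls += conv.call_sequence_convergence(an_cn, ar_co, mark)

    # expression divergence and convergence
    div_rows = []
    expr_conv: dict = {}
    for tet in tetrads:
        tpm = {g: bundle.expression[g].get(tet.genes[g], 0.0)
               for g in GENOME_LABELS}
        for pair, (ga, gb) in PAIR_MEMBERS.items():
            div_rows.append({
                "tetrad_id": tet.tetrad_id, "pair": pair,
                "log2fc": round(log2_fold_change(tpm[ga], tpm[gb]), 6),
                "tpm_diff": round(abs(tpm[ga] - tpm[gb]), 6)})
        expr_conv[tet.tetrad_id] = conv.call_expression_convergence(
            tpm["Ar"], tpm["Co"], tpm["An"], tpm["Cn"],
            fc_threshold=th.fc_threshold)
    divergence = pd.DataFrame(div_rows)

    # TFBS scanning, conservation scores, variants
    tetrad_gene_sets = {g: {tet.genes[g] for tet in tetrads}
                        for g in GENOME_LABELS}
    motif_hits = {g: {} for g in GENOME_LABELS}
    for g in GENOME_LABELS:
        for tet in tetrads:
            gid = tet.genes[g]
            motif_hits[g][gid] = scan_promoter_all(
                promoters[g][gid].sequence, bundle.pwms, gene_id=gid,
                threshold=th.motif_score)
    cs_scores = {"An": [], "Cn": []}
    variants: dict = {}
    var_len_by_gene = {"An": {}, "Cn": {}}
    cs_by_gene = {"An": {}, "Cn": {}}
    for tet in tetrads:
        for sub, dip, pair in (("An", "Ar", "Ar-An"), ("Cn", "Co", "Co-Cn")):
            gid_t, gid_d = tet.genes[sub], tet.genes[dip]
            hits_t = motif_hits[sub][gid_t]
            hits_d = motif_hits[dip][gid_d]
            score = tfbs_conservation_score(hits_t, hits_d, gene_id=gid_t)
            cs_scores[sub].append(score)
            vs = call_variants(alignments[(tet.tetrad_id, pair)])
            diploid_motifs = {h.motif_id for h in hits_d}
            conserved_flags = [h.motif_id in diploid_motifs for h in hits_t]
            overlap_with_tfbs(vs, [h.window for h in hits_t], conserved_flags)
            variants[(tet.tetrad_id, pair)] = vs
            var_len_by_gene[sub][gid_t] = float(sum(v.length for v in vs))
            if score.cs is not None:
                cs_by_gene[sub][gid_t] = score.cs

    summary = _summarise(tetrads, pair_calls, convergence_calls, expr_conv,
                         divergence, cs_scores, variants, motif_hits,
                         tetrad_gene_sets, peak_map, bundle, th,
                         var_len_by_gene, cs_by_gene)
    log.info("pipeline complete (%.1fs)", time.time() - t0)
    return PipelineResult(tetrads=tetrads, pair_calls=pair_calls,
                          convergence_calls=convergence_calls,
                          expression_convergence=expr_conv,
                          divergence=divergence, cs_scores=cs_scores,
                          variants=variants, motif_hits=motif_hits,
                          summary=summary)


def _summarise(tetrads, pair_calls, convergence_calls, expr_conv, divergence,
               cs_scores, variants, motif_hits, tetrad_gene_sets, peak_map,
               bundle, th, var_len_by_gene, cs_by_gene) -> dict:
    summary: dict = {"n_tetrads": len(tetrads)}

    # class proportions per pair axis and mark
    proportions = {}
    for pair in PAIR_MEMBERS:
        for mark in CLASS_MARKS:
            try:
                proportions[f"{pair}:{mark}"] = pc.class_proportions(
                    pair_calls, pair, mark)
            except ValueError:
                continue
    summary["class_proportions"] = proportions

    # convergence categories per mark and layer
    categories: dict = {}
    for layer in ("epigenomic", "sequence"):
        for mark in CLASS_MARKS:
            sel = [c for c in convergence_calls
                   if c.layer == layer and c.mark == mark]
            if sel:
                categories[f"{layer}:{mark}"] = conv.category_summary(sel)
    summary["convergence_categories"] = categories
    summary["expression_convergent_fraction"] = (
        sum(expr_conv.values()) / len(expr_conv) if expr_conv else float("nan"))

    # marked-gene counts per genome and mark (genes with >=1 promoter peak)
    marked = {}
    for g in GENOME_LABELS:
        for mark in MARKS:
            marked[f"{g}:{mark}"] = sum(
                1 for tet in tetrads if peak_map[g][tet.genes[g]][mark])
    summary["marked_gene_counts"] = marked

    # signal-expression correlation per mark (peak score proxy: total peak
    # span in promoter; 0 when unmarked)
    corr = {}
    for mark in MARKS:
        sig, tpms = [], []
        for tet in tetrads:
            gid = tet.genes["An"]
            ivs = peak_map["An"][gid][mark]
            sig.append(float(sum(e - s for s, e in ivs)))
            tpms.append(bundle.expression["An"].get(gid, 0.0))
        try:
            r, p = signal_expression_correlation(sig, tpms)
            corr[mark] = {"r": round(r, 4), "p": p}
        except ValueError:
            corr[mark] = None
    summary["signal_expression_correlation"] = corr

    # TFBS
    cs_summary = {}
    for sub in ("An", "Cn"):
        defined = [s.cs for s in cs_scores[sub] if s.cs is not None]
        cs_summary[sub] = {
            "n": len(defined),
            "mean_cs": float(np.mean(defined)) if defined else float("nan"),
            "high_fraction": (high_conservation_fraction(cs_scores[sub], th.cs_cutoff)
                              if defined else float("nan"))}
    summary["tfbs_conservation"] = cs_summary
    counts = tf_target_counts(
        {g: [h for hits in motif_hits[g].values() for h in hits]
         for g in GENOME_LABELS}, tetrad_gene_sets)
    summary["tf_target_comparisons"] = target_count_comparison(counts)
    summary["tfbs_totals"] = {g: int(sum(len(h) for h in motif_hits[g].values()))
                              for g in GENOME_LABELS}

    # variants
    var_summary = {}
    for pair in ("Ar-An", "Co-Cn"):
        vs = [v for (tid, p), lst in variants.items() if p == pair for v in lst]
        per_type = {}
        for vtype in ("SNV", "InDel", "SV"):
            of_type = [v for v in vs if v.vtype == vtype]
            per_type[vtype] = {
                "count": len(of_type),
                "overlap_fraction": (
                    sum(v.overlaps_nonconserved_tfbs for v in of_type) / len(of_type)
                    if of_type else float("nan"))}
        var_summary[pair] = per_type
    summary["variants"] = var_summary
    for sub in ("An", "Cn"):
        try:
            rho, p = variation_length_vs_cs(var_len_by_gene[sub], cs_by_gene[sub])
            summary[f"variation_vs_cs_{sub}"] = {"rho": round(rho, 4), "p": p}
        except ValueError:
            summary[f"variation_vs_cs_{sub}"] = None
    return summary


def write_run(result: PipelineResult, outdir: str | Path,
              config: dict | None = None, seed: int | None = None) -> Path:
    """Write all result tables, the summary and a reproducibility manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = write_results(result.tables(), outdir)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "config": config,
        "tables": {name: sha256_file(path) for name, path in sorted(written.items())},
        "summary_sha256": sha256_file(outdir / "summary.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
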