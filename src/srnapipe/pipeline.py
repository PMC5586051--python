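"""Pipeline orchestration: stage composition, config, manifest.

The stages run in fixed order (preprocess -> annotate -> novel -> de ->
target -> degradome -> enrich), each reading only files and the shared
in-memory tag table, so a pipeline run equals the composition of the
individual stage functions with identical parameters. Every output TSV
is reproducible byte-identically for identical (inputs, config, seed);
a machine-readable manifest records the config hash and per-stage row
counts so the conservation invariants are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotate_known import (DEFAULT_CLASS_ORDER, MirbaseDB, ReferenceSet,
                             annotate_tags)
from .degradome import map_tags, report_validated_pairs
from .expression_stats import benjamini_hochberg, call_de, hypergeom_enrich
from .novel_hairpin import call_novel, excise_candidates
from .preprocess import CleaningConfig, clean_reads, length_distribution
from .sio import (Annotation, CountMatrix, TagRecord, read_collapsed_fasta,
                  read_degradome_tags, read_fasta, read_fastq,
                  read_term_table, write_collapsed_fasta, write_site_report)
from .target_duplex import RulesConfig, scan_transcript

STAGES = ["preprocess", "annotate", "novel", "de", "target", "degradome",
          "enrich"]


@dataclass
class PipelineConfig:
    """All inputs, outputs and thresholds of one pipeline run.

    Thresholds default to the standard values of the analysis this
    package implements: clean-read lengths 18-30 nt, 16-nt known-miRNA
    overlap, <= 2 cross-species mismatches/gaps, MFEI >= 0.9, the
    six-rule parameters (<= 4 mismatches, <= 2.5 in positions 1-12,
    energy ratio >= 0.75), |log2FC| >= 1 with p < 1e-5 for differential
    expression, enrichment p < 0.05, and a +/-1 nt degradome window with
    >= 2 supporting reads.
    """

    output_dir: str = "run"
    srna_libraries: dict[str, str] = field(default_factory=dict)
    genome_fasta: str | None = None
    transcripts_fasta: str | None = None
    degradome_tags: str | None = None
    mirbase_mature: str | None = None
    mirbase_hairpin: str | None = None
    reference_fastas: dict[str, str] = field(default_factory=dict)
    term_table: str | None = None
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    min_len: int = 18
    max_len: int = 30
    adapter_5p: str = ""
    adapter_3p: str = ""
    species: str = "hvu"
    min_overlap: int = 16
    overlap_mismatches: int = 0
    cross_budget: int = 2
    flank: int = 250
    min_mfei: float = 0.9
    min_novel_reads: int = 5
    novel_min_len: int = 18
    novel_max_len: int = 26
    max_mismatch: float = 4.0
    max_5p_mismatch: float = 2.5
    min_energy_ratio: float = 0.75
    gu_is_mismatch: bool = False
    de_pair: tuple[str, str] | None = None
    fc_threshold: float = 1.0
    alpha: float = 1e-5
    de_method: str = "audic_claverie"
    enrich_alpha: float = 0.05
    degradome_window: int = 1
    degradome_min_reads: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.de_pair is not None:
            cfg.de_pair = tuple(cfg.de_pair)
        return cfg

    def validate(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("bad length bounds")
        if not 0 <= self.min_energy_ratio <= 1:
            raise ValueError("energy ratio must be in [0, 1]")
        for p in self._input_paths():
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input: {p}")

    def _input_paths(self):
        paths = list(self.srna_libraries.values())
        paths += list(self.reference_fastas.values())
        for p in (self.genome_fasta, self.transcripts_fasta,
                  self.degradome_tags, self.mirbase_mature,
                  self.mirbase_hairpin, self.term_table):
            if p:
                paths.append(p)
        return paths

    def config_hash(self) -> str:
        """Hash of the analytic parameters (the output location is not
        part of a run's identity)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def rules_config(self) -> RulesConfig:
        return RulesConfig(max_mismatch=self.max_mismatch,
                           max_5p_mismatch=self.max_5p_mismatch,
                           min_energy_ratio=self.min_energy_ratio,
                           gu_is_mismatch=self.gu_is_mismatch)


def _read_reads(path: str):
    p = Path(path)
    name = p.name.lower()
    if name.endswith((".fastq", ".fq", ".fastq.gz", ".fq.gz")):
        return read_fastq(p)
    try:
        return read_collapsed_fasta(p)
    except ValueError:
        return read_fasta(p)


def _write_tsv(path: Path, header: list[str], rows) -> int:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        n = 0
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
            n += 1
    return n


class PipelineRun:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.tags: dict[str, TagRecord] = {}
        self.library_totals: dict[str, int] = {}
        self.known_calls: dict[str, object] = {}
        self.novel_calls: dict[str, object] = {}
        self.sites = []
        self.validated = []
        self.counts = {}   # stage -> rows written

    # -- stages -------------------------------------------------------------

    def stage_preprocess(self) -> None:
        cfg = self.config
        clean_cfg = CleaningConfig(cfg.min_len, cfg.max_len,
                                   cfg.adapter_5p, cfg.adapter_3p)
        for lib, path in sorted(cfg.srna_libraries.items()):
            reads = _read_reads(path)
            tags, stats = clean_reads(reads, clean_cfg, library=lib)
            self.library_totals[lib] = stats.kept_reads
            for t in tags:
                rec = self.tags.setdefault(t.sequence,
                                           TagRecord(t.sequence, {}))
                rec.counts[lib] = rec.counts.get(lib, 0) + t.counts[lib]
            write_collapsed_fasta(tags, self.out / f"clean_{lib}.fa",
                                  library=lib)
            dist = length_distribution(tags)
            _write_tsv(self.out / f"lengths_{lib}.tsv",
                       ["length", "reads", "fraction"],
                       [(ln, n, f"{f:.6f}") for ln, (n, f) in dist.items()])
            (self.out / f"cleaning_{lib}.json").write_text(
                json.dumps(stats.as_dict(), indent=1))
        self.counts["preprocess"] = len(self.tags)

    def stage_annotate(self) -> None:
        cfg = self.config
        refs = [ReferenceSet(Annotation(label), read_fasta(path))
                for label, path in cfg.reference_fastas.items()]
        order = {lab: i for i, lab in enumerate(DEFAULT_CLASS_ORDER)}
        refs.sort(key=lambda r: order.get(r.label, 99))
        db = None
        if cfg.mirbase_mature and cfg.mirbase_hairpin:
            db = MirbaseDB(read_fasta(cfg.mirbase_mature),
                           read_fasta(cfg.mirbase_hairpin))
        genome = read_fasta(cfg.genome_fasta) if cfg.genome_fasta else None
        tags = sorted(self.tags.values(), key=lambda t: t.sequence)
        self.known_calls = annotate_tags(
            tags, refs, db, cfg.species, genome=genome,
            min_overlap=cfg.min_overlap,
            overlap_mismatches=cfg.overlap_mismatches,
            cross_budget=cfg.cross_budget)
        _write_tsv(self.out / "annotation.tsv",
                   ["sequence", "annotation", "total_reads"],
                   [(t.sequence, t.annotation.value, t.total_count)
                    for t in tags])
        self.counts["annotate"] = _write_tsv(
            self.out / "known_mirnas.tsv",
            ["sequence", "miRNA", "mode", "mismatches"],
            [(s, c.mirna_id, c.mode, f"{c.mismatches:g}")
             for s, c in sorted(self.known_calls.items())])

    def stage_novel(self) -> None:
        cfg = self.config
        if not cfg.genome_fasta:
            self.counts["novel"] = 0
            return
        genome = read_fasta(cfg.genome_fasta)
        rows = []
        for seq in sorted(self.tags):
            tag = self.tags[seq]
            if tag.annotation not in (Annotation.UNASSIGNED,
                                      Annotation.EXON, Annotation.INTRON):
                continue
            if not (cfg.novel_min_len <= len(seq) <= cfg.novel_max_len):
                continue
            if tag.total_count < cfg.min_novel_reads:
                continue
            wins = excise_candidates(seq, genome, flank=cfg.flank)
            cand = call_novel(seq, wins, min_mfei=cfg.min_mfei)
            if cand is None:
                continue
            tag.annotation = Annotation.NOVEL_MIRNA
            self.novel_calls[seq] = cand
            win = cand.window
            rows.append((seq,
                         win.chrom if win else "", win.g_start if win else "",
                         win.g_end if win else "",
                         win.strand if win else "", cand.arm,
                         f"{cand.mfe:.2f}", f"{cand.mfei:.3f}",
                         len(cand.seq)))
        self.counts["novel"] = _write_tsv(
            self.out / "novel_mirnas.tsv",
            ["sequence", "chrom", "window_start", "window_end", "strand",
             "arm", "MFE", "MFEI", "precursor_len"], rows)

    def _mirna_tags(self) -> list[TagRecord]:
        mir = [t for t in self.tags.values()
               if t.annotation in (Annotation.KNOWN_MIRNA,
                                   Annotation.NOVEL_MIRNA)]
        return sorted(mir or self.tags.values(), key=lambda t: t.sequence)

    def _mirna_name(self, seq: str) -> str:
        if seq in self.known_calls:
            return self.known_calls[seq].mirna_id
        return f"novel:{seq[:8]}" if seq in self.novel_calls else seq

    def stage_de(self) -> None:
        cfg = self.config
        libs = sorted(self.library_totals)
        pair = cfg.de_pair or (tuple(libs[:2]) if len(libs) >= 2 else None)
        if pair is None:
            self.counts["de"] = 0
            return
        matrix = CountMatrix.from_tags(self._mirna_tags(),
                                       self.library_totals, libraries=libs)
        matrix.to_tsv(self.out / "counts.tsv")
        results = call_de(matrix, pair, cfg.fc_threshold, cfg.alpha,
                          cfg.de_method)
        self.counts["de"] = _write_tsv(
            self.out / "de.tsv",
            ["feature", f"count_{pair[0]}", f"count_{pair[1]}",
             f"tpm_{pair[0]}", f"tpm_{pair[1]}", "log2fc", "p_value",
             "significant"],
            [(self._mirna_name(r.feature_id), r.count_a, r.count_b,
              f"{r.tpm_a:.2f}", f"{r.tpm_b:.2f}", f"{r.log2fc:.3f}",
              f"{r.p_value:.3g}", "yes" if r.significant else "no")
             for r in results])

    def stage_target(self) -> None:
        cfg = self.config
        if not cfg.transcripts_fasta:
            self.counts["target"] = 0
            return
        transcripts = read_fasta(cfg.transcripts_fasta)
        rules = cfg.rules_config()
        self.sites = []
        for tag in self._mirna_tags():
            name = self._mirna_name(tag.sequence)
            for tid, tseq in transcripts:
                self.sites.extend(scan_transcript(
                    tag.sequence, tseq, rules, transcript_id=tid,
                    mirna_id=name))
        from .target_duplex import site_to_report
        write_site_report([site_to_report(s) for s in self.sites],
                          self.out / "target_sites.tsv")
        self.counts["target"] = len(self.sites)

    def stage_degradome(self) -> None:
        cfg = self.config
        if not (cfg.degradome_tags and cfg.transcripts_fasta):
            self.counts["degradome"] = 0
            return
        tags = read_degradome_tags(cfg.degradome_tags)
        transcripts = read_fasta(cfg.transcripts_fasta)
        profiles = map_tags(tags, transcripts)
        self.validated = report_validated_pairs(
            self.sites, profiles, window=cfg.degradome_window,
            min_reads=cfg.degradome_min_reads)
        write_site_report(self.validated, self.out / "validated_sites.tsv")
        self.counts["degradome"] = len(self.validated)

    def stage_enrich(self) -> None:
        cfg = self.config
        if not (cfg.term_table and cfg.transcripts_fasta):
            self.counts["enrich"] = 0
            return
        table = read_term_table(cfg.term_table)
        background = [tid for tid, _ in read_fasta(cfg.transcripts_fasta)]
        hits = self.validated or self.sites
        study = sorted({getattr(r, "transcript_id") for r in hits})
        results = hypergeom_enrich(study, background, table)
        qs = benjamini_hochberg([r.p_value for r in results])
        self.counts["enrich"] = _write_tsv(
            self.out / "enrichment.tsv",
            ["term", "k", "n", "K", "N", "p_value", "bh_q",
             "significant"],
            [(r.term, r.k, r.n, r.K, r.N, f"{r.p_value:.4g}", f"{q:.4g}",
              "yes" if r.p_value < cfg.enrich_alpha else "no")
             for r, q in zip(results, qs)])


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the enabled stages in fixed order; returns the run directory.

    Missing inputs fail before any stage runs. A stage error leaves the
    partial outputs in place and records the failure point in the
    manifest before re-raising.
    """
    config.validate()
    run = PipelineRun(config)
    run.out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "srnapipe", "version": __version__,
        "config_hash": config.config_hash(), "seed": config.seed,
        "stages_run": [], "row_counts": {}, "failed_stage": None,
    }
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            getattr(run, f"stage_{stage}")()
            manifest["stages_run"].append(stage)
            manifest["row_counts"][stage] = run.counts.get(stage, 0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (run.out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        raise
    (run.out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return run.out
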