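"""End-to-end orchestration: per-species scan -> genome summaries ->
comparative statistics, with a run manifest and clean stage skipping.

Library code logs through the ``fiveprime`` logger and never prints.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import comparative_stats as cs
from . import genome_io, zscore_scan
from .folding import get_backend
from .shuffling import ShuffleConfig
from .zscore_scan import WindowSpec

logger = logging.getLogger("fiveprime")

MANIFEST_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable run configuration; a saved config plus the same
    inputs reproduces a run exactly."""

    window: WindowSpec = field(default_factory=WindowSpec)
    shuffle: ShuffleConfig = field(default_factory=ShuffleConfig)
    backend: str = "vienna"
    min_codons: int = genome_io.DEFAULT_MIN_CODONS
    stratify_fraction: float = 0.05
    exclude_taxa: tuple[str, ...] = tuple(sorted(cs.DEFAULT_TAXON_EXCLUSIONS))
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclude_taxa"] = list(self.exclude_taxa)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "window" in d:
            d["window"] = WindowSpec(**d["window"])
        if "shuffle" in d:
            d["shuffle"] = ShuffleConfig(**d["shuffle"])
        if "exclude_taxa" in d:
            d["exclude_taxa"] = tuple(d["exclude_taxa"])
        return cls(**d)

    def save_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_species(
    fasta: Path,
    config: RunConfig,
    outdir: Path,
    backend=None,
) -> list[zscore_scan.GenomeSummary]:
    """Scan one species' CDS file and write its window tables."""
    if backend is None:
        backend = get_backend(config.backend)
    species_id = fasta.stem
    shuffle = dataclasses.replace(config.shuffle, seed=config.seed)
    genes, report = genome_io.read_cds_fasta(fasta, config.min_codons, species_id)
    if not genes:
        raise ValueError(f"no usable genes in {fasta}")
    report.write_tsv(outdir / f"{species_id}.rejections.tsv")
    profiles = zscore_scan.scan_genes(genes, config.window, shuffle, backend)
    zscore_scan.profiles_to_frame(profiles).to_csv(
        outdir / f"{species_id}.gene_windows.tsv", sep="\t", index=False
    )
    summaries = zscore_scan.summarize_genome(profiles, species_id)
    zscore_scan.summaries_to_frame(summaries).to_csv(
        outdir / f"{species_id}.genome_summary.tsv", sep="\t", index=False
    )

    annots = cs.annotate_genes(genes, profiles)
    strat_rows = []
    for criterion in ("gc", "enc"):
        try:
            comp = cs.stratify(annots, criterion, config.stratify_fraction)
            strat_rows.append(vars(comp))
        except ValueError as exc:
            logger.warning("%s: stratify %s skipped: %s", species_id, criterion, exc)
    if strat_rows:
        pd.DataFrame(strat_rows).to_csv(
            outdir / f"{species_id}.stratified.tsv", sep="\t", index=False
        )
    return summaries


def run_all(config: RunConfig, input_dir: str | Path, outdir: str | Path) -> Path:
    """Run the full pipeline over a directory of per-species FASTA files.

    ``input_dir`` holds one ``<species_id>.fasta`` per species and optionally
    ``metadata.tsv``.  Stages whose outputs already exist under an identical
    config/input hash are skipped.  A failing species is logged and listed in
    the manifest without aborting the panel.
    """
    input_dir = Path(input_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fastas = sorted(input_dir.glob("*.fasta"))
    input_hashes = {f.name: _sha256(f) for f in fastas}
    meta_path = input_dir / "metadata.tsv"
    if meta_path.exists():
        input_hashes[meta_path.name] = _sha256(meta_path)
    cfg_hash = _config_hash(config)

    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if (
            old.get("config_hash") == cfg_hash
            and old.get("input_hashes") == input_hashes
            and not old.get("failures")
        ):
            logger.info("outputs up to date; skipping run")
            return outdir

    backend = get_backend(config.backend)
    all_summaries: dict[str, list[zscore_scan.GenomeSummary]] = {}
    genomic_gc: dict[str, float] = {}
    failures: dict[str, str] = {}
    for fasta in fastas:
        sp = fasta.stem
        try:
            genes, _ = genome_io.read_cds_fasta(fasta, config.min_codons, sp)
            genomic_gc[sp] = genome_io.compute_genomic_gc(genes)
            all_summaries[sp] = run_species(fasta, config, outdir, backend)
        except Exception as exc:
            logger.error("species %s failed: %s", sp, exc)
            failures[sp] = str(exc)

    summary_frames = [
        zscore_scan.summaries_to_frame(s) for s in all_summaries.values()
    ]
    if summary_frames:
        pd.concat(summary_frames, ignore_index=True).to_csv(
            outdir / "genome_summary.tsv", sep="\t", index=False
        )

    if meta_path.exists() and all_summaries:
        metadata = genome_io.read_metadata(meta_path)
        metadata = [
            dataclasses.replace(m, genomic_gc=genomic_gc.get(m.species_id, m.genomic_gc))
            for m in metadata
        ]
        genome_io.write_metadata(metadata, outdir / "metadata_enriched.tsv")
        points = cs.species_points(all_summaries, metadata)
        cs.cross_species_analysis(points, config.exclude_taxa).to_csv(
            outdir / "correlations.tsv", sep="\t", index=False
        )

    manifest = {
        "manifest_version": MANIFEST_VERSION,
        "config_hash": cfg_hash,
        "config": config.to_dict(),
        "input_hashes": input_hashes,
        "n_species": len(all_summaries),
        "failures": failures,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
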