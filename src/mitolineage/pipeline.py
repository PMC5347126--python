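"""End-to-end orchestration: FASTA -> variants -> haplogroups -> trees -> TMRCA.

`run_pipeline` is the library entry point behind the command-line interface.
It reads whole-mitogenome FASTA, calls variants against the packaged
reference, classifies every sample, builds one maximum-parsimony tree per
observed clade (a clade's members are the samples assigned to it or to any
of its descendants) and writes a TMRCA report per configured clock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml
from Bio import SeqIO

from . import calling, classify, haplotree, mptree, tmrca
from .classify import SiteWeights, default_classification_weights
from .reference import DEFAULT_MASK
from .synthetic_reference import load_reference
from .variants import VariantProfile

logger = logging.getLogger("mitolineage.pipeline")


class PipelineError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    fasta: Optional[str] = None
    tree: str = "australia_2017"          # packaged tree name or a file path
    out_dir: str = "mitolineage_out"
    clocks: Optional[Sequence[str]] = None  # names from the clock config
    clock_file: Optional[str] = None
    mask: frozenset[int] = frozenset(DEFAULT_MASK)
    band: int = calling.DEFAULT_BAND
    length_tolerance: int = 100
    seed: int = 0                          # used by the simulate subcommand
    verbosity: int = logging.INFO

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "mask" in data:
            data["mask"] = frozenset(int(p) for p in data["mask"])
        return cls(**data)


@dataclass
class ReportBundle:
    classification_tsv: Path
    tmrca_tsv: Path
    newick_dir: Path
    results: list[classify.ClassificationResult]
    estimates: list[tmrca.RhoEstimate]


def _load_tree(name_or_path: str) -> haplotree.HaploTree:
    p = Path(name_or_path)
    if p.exists():
        return haplotree.load_haplotree(p)
    return haplotree.load_packaged_tree(name_or_path)


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "pipeline.log", cfg.verbosity)

    if not cfg.fasta:
        raise PipelineError("config", "no input FASTA given")
    records = list(SeqIO.parse(cfg.fasta, "fasta"))
    if not records:
        raise PipelineError("input", f"no FASTA records in {cfg.fasta}")

    reference = load_reference()
    tree = _load_tree(cfg.tree)
    weights = default_classification_weights(cfg.mask)
    clock_table = tmrca.load_clocks(cfg.clock_file)
    clocks = [
        clock_table[name] for name in (cfg.clocks or list(clock_table))
    ]

    logger.info("calling variants for %d samples (mask: %d sites)",
                len(records), len(cfg.mask))
    for pos in sorted(cfg.mask):
        logger.info("masked site np %d", pos)

    profiles: list[VariantProfile] = []
    for rec in records:
        try:
            profiles.append(
                calling.call_variants(
                    str(rec.seq), reference, sample_id=rec.id, mask=cfg.mask,
                    length_tolerance=cfg.length_tolerance, band=cfg.band,
                )
            )
        except Exception as exc:
            raise PipelineError("call", f"sample {rec.id}: {exc}") from exc

    results = []
    for p in profiles:
        try:
            r = classify.classify_sample(p, tree, weights)
        except Exception as exc:
            raise PipelineError("classify", f"sample {p.sample_id}: {exc}") from exc
        if r.tied:
            logger.warning("sample %s: classification tie between %s and %s",
                           p.sample_id, r.haplogroup, ", ".join(r.tied))
        results.append(r)

    classification_tsv = out / "classification.tsv"
    classify.write_classification_tsv(results, classification_tsv)
    calling.write_profiles_tsv(profiles, out / "variants.tsv")

    assigned = {r.sample_id: r.haplogroup for r in results}
    clades = sorted({r.haplogroup for r in results})
    newick_dir = out / "trees"
    newick_dir.mkdir(exist_ok=True)
    estimates: list[tmrca.RhoEstimate] = []
    for clade in clades:
        try:
            ests = tmrca.estimate_clade_tmrca(
                profiles, tree, clade, clocks, weights, preclassified=assigned
            )
        except Exception as exc:
            raise PipelineError("tmrca", f"clade {clade}: {exc}") from exc
        if not ests:
            logger.warning("clade %s: no samples, skipped", clade)
            continue
        estimates.extend(ests)
        members = [p for p in profiles
                   if assigned[p.sample_id] in ({clade} | set(tree.descendants(clade)))]
        root_profile = VariantProfile(
            sample_id=f"root_{clade}",
            variants=haplotree.cumulative_expected(tree, clade),
        )
        stree = mptree.build_mp_tree(members, root_profile, weights)
        (newick_dir / f"{clade}.nwk").write_text(mptree.to_newick(stree) + "\n")

    tmrca_tsv = out / "tmrca.tsv"
    tmrca.write_tmrca_table(estimates, tmrca_tsv)
    logger.info("wrote %s, %s and %d clade trees",
                classification_tsv.name, tmrca_tsv.name, len(clades))
    return ReportBundle(
        classification_tsv=classification_tsv,
        tmrca_tsv=tmrca_tsv,
        newick_dir=newick_dir,
        results=results,
        estimates=estimates,
    )


def _setup_logging(logfile: Path, level: int) -> None:
    root = logging.getLogger("mitolineage")
    root.setLevel(level)
    have_file = any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == logfile.resolve()
        for h in root.handlers
    )
    if not have_file:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        root.addHandler(fh)
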