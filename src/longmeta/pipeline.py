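"""End-to-end orchestration: per-sample profiling and cohort analysis.

`run_profile` takes one sample's classifier output and alignments and
writes the validation table, filtered composition, domain fractions and the
targeted ARG / crAssphage quantifications.  `run_cohort` consumes the
per-sample results of several samples plus metadata and produces the
community-level outputs (distances, ordination, cluster scan, follow-up
membership) and, when allele counts are supplied, the strain-replacement
calls with their event association.

Configuration lives in one YAML file; every numeric threshold in the
outputs traces back to it, and the seed is recorded in each output header.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import community as _community
from . import composition as _composition
from .alignments import index_by_query, parse_paf
from .strain import (
    StrainConfig,
    aani_lowfreq,
    event_association,
    make_interval_calls,
    read_allele_counts_tsv,
)
from .targeted import count_arg_reads, crassphage_profile
from .taxonomy import TaxonomyTree, load_taxonomy, parse_kraken_assignments
from .validation import (
    ValidationConfig,
    results_to_frame,
    validate_sample,
)

__all__ = ["RunConfig", "run_profile", "run_cohort", "load_run_config"]


@dataclass
class RunConfig:
    """Pipeline-wide configuration (defaults = the published thresholds)."""

    seed: int = 0
    output_dir: str = "longmeta_out"
    validation: ValidationConfig = field(
        default_factory=lambda: ValidationConfig()
    )
    strain: StrainConfig = field(default_factory=StrainConfig)
    min_reads: int = 5
    k_range: tuple[int, int] = (2, 6)
    kmeans_restarts: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        validation = ValidationConfig(**raw.pop("validation", {}))
        strain = StrainConfig(**raw.pop("strain", {}))
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(validation=validation, strain=strain, **raw)


def load_run_config(path: str | Path) -> RunConfig:
    return RunConfig.from_yaml(path)


def _write_with_header(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# longmeta seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t")


def _log(out_dir: Path, stage: str, started: float, **info) -> None:
    entry = {
        "stage": stage,
        "wall_s": round(time.monotonic() - started, 3),
        **info,
    }
    with open(out_dir / "pipeline.log", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def run_profile(
    cfg: RunConfig,
    sample_id: str,
    *,
    kraken_path: str | Path,
    paf_path: str | Path,
    nodes_path: str | Path,
    names_path: str | Path | None = None,
    target_taxids: Mapping[str, int] | None = None,
    arg_paf_path: str | Path | None = None,
    crass_paf_path: str | Path | None = None,
) -> dict[str, Path]:
    """Profile one sample end to end; returns the written output paths.

    Missing mandatory inputs fail fast with the offending path.  A sample
    with zero classified reads yields empty tables and a warning entry in
    the log, but exits successfully.
    """
    for p in (kraken_path, paf_path, nodes_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input: {p}")
    out_dir = Path(cfg.output_dir) / sample_id
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.monotonic()

    tree = load_taxonomy(nodes_path, names_path)
    assignments = parse_kraken_assignments(kraken_path)
    alignments = index_by_query(parse_paf(paf_path))
    outputs: dict[str, Path] = {}

    n_classified = sum(a.classified for a in assignments)
    if n_classified == 0:
        for name in ("validation", "composition", "domains"):
            path = out_dir / f"{name}.tsv"
            _write_with_header(pd.DataFrame(), path, cfg)
            outputs[name] = path
        _log(out_dir, "profile", started, sample=sample_id,
             warning="zero classified reads")
        return outputs

    vcfg = ValidationConfig(
        **{**asdict(cfg.validation), "seed": cfg.seed}
    )
    results = validate_sample(
        tree, assignments, alignments, vcfg, target_taxids=target_taxids
    )
    vframe = results_to_frame(results).set_index("taxid")
    outputs["validation"] = out_dir / "validation.tsv"
    _write_with_header(vframe, outputs["validation"], cfg)

    table = _composition.build_species_table(
        {sample_id: assignments},
        {sample_id: results},
        tree,
        min_reads=cfg.min_reads,
    )
    outputs["composition"] = out_dir / "composition.tsv"
    _write_with_header(table, outputs["composition"], cfg)

    domains = _composition.domain_fractions(assignments, tree)
    dframe = pd.DataFrame(
        [{"domain": k.value, "fraction": v} for k, v in domains.items()]
    ).set_index("domain")
    outputs["domains"] = out_dir / "domains.tsv"
    _write_with_header(dframe, outputs["domains"], cfg)

    total_reads = len(assignments)
    if arg_paf_path is not None:
        arg = count_arg_reads(parse_paf(arg_paf_path), total_reads)
        aframe = pd.DataFrame(
            [{"arg_id": k, "reads": v} for k, v in arg.per_arg.items()]
        )
        aframe.loc[len(aframe)] = ["__rate_per_10k__", arg.rate_per_10k]
        outputs["arg"] = out_dir / "arg.tsv"
        _write_with_header(aframe.set_index("arg_id"), outputs["arg"], cfg)
    if crass_paf_path is not None:
        crass = crassphage_profile(parse_paf(crass_paf_path), total_reads)
        cframe = pd.DataFrame(
            [{"strain": k, "reads": v} for k, v in crass.per_strain.items()]
            + [
                {"strain": "__abundance__", "reads": crass.abundance},
                {
                    "strain": "__assignable_fraction__",
                    "reads": crass.assignable_fraction,
                },
            ]
        ).set_index("strain")
        outputs["crass"] = out_dir / "crass.tsv"
        _write_with_header(cframe, outputs["crass"], cfg)

    _log(out_dir, "profile", started, sample=sample_id,
         n_reads=total_reads, n_taxa=len(results))
    return outputs


def run_cohort(
    cfg: RunConfig,
    composition_table: pd.DataFrame,
    metadata: pd.DataFrame,
    *,
    baseline_samples: Sequence[str] | None = None,
    allele_counts: Mapping[str, Mapping[str, "object"]] | None = None,
    events: pd.DataFrame | None = None,
) -> dict[str, object]:
    """Cohort-level analysis over per-sample compositions.

    ``composition_table`` is the output of
    :func:`longmeta.composition.build_species_table` over all samples;
    ``metadata`` needs columns sample_id, patient, day.  With fewer than 3
    samples the cluster scan is skipped (distances are still computed).
    ``allele_counts`` maps species -> {sample_id -> AlleleCounts} and
    triggers the strain-replacement analysis when given together with
    ``events``.
    """
    known = set(composition_table.index.astype(str))
    orphans = sorted(
        set(metadata["sample_id"].astype(str)).symmetric_difference(known)
    )
    if orphans:
        raise ValueError(f"metadata/sample mismatch: {orphans}")

    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.monotonic()
    results: dict[str, object] = {}

    vectors = _composition.abundance_vectors(composition_table)
    dm = _community.bray_curtis_matrix(vectors)
    results["distances"] = dm
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        out_dir / "bray_curtis.tsv", sep="\t"
    )

    ordination = _community.pcoa(dm)
    results["ordination"] = ordination
    _write_with_header(
        ordination.coordinates_frame(), out_dir / "pcoa.tsv", cfg
    )

    if len(vectors) >= 4:
        clusters = _community.scan_kmeans(
            ordination,
            k_range=cfg.k_range,
            seed=cfg.seed,
            restarts=cfg.kmeans_restarts,
            sample_ids=baseline_samples,
        )
        results["clusters"] = clusters
        sil = pd.DataFrame(
            sorted(clusters.silhouette_by_k.items()),
            columns=["k", "silhouette"],
        ).set_index("k")
        _write_with_header(sil, out_dir / "silhouette.tsv", cfg)
        labels = pd.DataFrame(
            sorted(clusters.labels.items()), columns=["sample_id", "cluster"]
        ).set_index("sample_id")
        _write_with_header(labels, out_dir / "clusters.tsv", cfg)
        if baseline_samples is not None:
            follow_up = [
                s for s in vectors.index.astype(str)
                if s not in set(map(str, baseline_samples))
            ]
            if follow_up:
                membership = _community.cluster_membership(
                    ordination, clusters.labels, follow_up
                )
                results["membership"] = membership
                _write_with_header(
                    membership, out_dir / "membership.tsv", cfg
                )
    else:
        results["clusters"] = None

    if allele_counts is not None:
        distances = {
            species: [
                aani_lowfreq(counts[s1], counts[s2], cfg.strain)
                for s1 in sorted(counts)
                for s2 in sorted(counts)
                if s1 != s2
            ]
            for species, counts in allele_counts.items()
        }
        calls = make_interval_calls(
            distances,
            metadata,
            events if events is not None
            else pd.DataFrame(columns=["patient", "day", "event"]),
            cfg.strain,
        )
        results["interval_calls"] = calls
        call_frame = pd.DataFrame([c.__dict__ for c in calls])
        if not call_frame.empty:
            _write_with_header(
                call_frame.set_index("sample_a"),
                out_dir / "strain_calls.tsv",
                cfg,
            )
        classified = [c for c in calls if c.replacement is not None]
        if classified:
            table, p = event_association(classified)
            results["event_association"] = (table, p)
            pd.DataFrame(
                table,
                index=["replacement", "no_replacement"],
                columns=["spans_event", "no_event"],
            ).to_csv(out_dir / "event_association.tsv", sep="\t")

    _log(out_dir, "cohort", started, n_samples=len(vectors))
    return results
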