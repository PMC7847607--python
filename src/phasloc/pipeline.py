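"""End-to-end orchestration: discovery, targets, RdDM, DCL calls.

The discovery flow mirrors the five-step screen the package implements:
map k-nt reads onto transcripts; find candidate regions of >= 5 tandem
occupied duplexes; keep regions whose best five-register window scores
strictly above 1; demand a dominant degradome cleavage signature at the
region flank/register; search and degradome-validate the sRNA trigger.
Validated 21-nt loci then feed phasiRNA enumeration, target prediction
and degradome validation of the interactions; mutant libraries, when
supplied, yield DCL-dependence calls.

Configuration is a flat mapping (YAML on disk); every threshold has a
documented default and is echoed to the run log.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import degradome as deg
from . import rddm as rddm_mod
from .dcl import DEFAULT_FOLD_THRESHOLD, DependenceCall, call_dependence
from .phase_model import (
    CandidateRegion,
    ReadPlacement,
    find_candidate_regions,
    map_reads,
)
from .phasing_score import SCORE_THRESHOLD, region_max_score, score_profile
from .seq_io import (
    SequenceRecord,
    SmallRNALibrary,
    normalize_rpm,
    read_fasta,
    read_srna_library,
)
from .tasirna import (
    PhasiRNA,
    TargetInteraction,
    build_network_table,
    enumerate_phasirnas,
    parse_phasirna_name,
    predict_targets,
    validate_interactions,
)
from .triggers import MAX_PENALTY, TriggerAlignment, find_trigger, validate_trigger

DEFAULT_PARAMS: dict = {
    "k_values": [21, 24],
    "min_duplexes": 5,
    "score_threshold": SCORE_THRESHOLD,
    "max_score": MAX_PENALTY,
    "min_rpm": deg.DEFAULT_MIN_RPM,
    "min_dominance": deg.DEFAULT_MIN_DOMINANCE,
    "flank_tolerance": 2,
    "fold_threshold": DEFAULT_FOLD_THRESHOLD,
    "cleavage_jitter": 0,
    "min_phasirna_rpm": 0.0,
}


class ConfigurationError(ValueError):
    """Missing or inconsistent pipeline configuration."""


@dataclass
class DiscoveredLocus:
    """A PHAS locus that survived every discovery filter."""

    region: CandidateRegion
    max_score: float
    cleavage_signals: list[deg.CleavageSignal]
    trigger: TriggerAlignment | None
    library_name: str
    placements: list[ReadPlacement] = field(default_factory=list)


@dataclass
class DiscoveryResult:
    loci: list[DiscoveredLocus]
    candidate_regions: list[CandidateRegion]
    profiles: dict[tuple[str, str], deg.DegradomeProfile]
    interactions: list[TargetInteraction] = field(default_factory=list)
    phasirnas: list[PhasiRNA] = field(default_factory=list)
    dcl_calls: list[DependenceCall] = field(default_factory=list)

    def loci_table(self) -> pd.DataFrame:
        rows = []
        for locus in self.loci:
            t = locus.trigger
            rows.append(
                {
                    "locus": locus.region.transcript_id,
                    "k": locus.region.k,
                    "region_start": locus.region.region_start,
                    "region_end": locus.region.region_end,
                    "anchor": locus.region.anchor,
                    "n_occupied_tandem": locus.region.n_occupied_tandem,
                    "max_phasing_score": locus.max_score,
                    "trigger_id": t.srna_id if t else "",
                    "trigger_sequence": t.srna_sequence if t else "",
                    "binding_start": t.binding_start if t else pd.NA,
                    "binding_end": t.binding_end if t else pd.NA,
                    "cleavage_site": t.predicted_cleavage if t else pd.NA,
                    "validated_by": ";".join(t.validating_libraries) if t else "",
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "locus", "k", "region_start", "region_end", "anchor",
                "n_occupied_tandem", "max_phasing_score", "trigger_id",
                "trigger_sequence", "binding_start", "binding_end",
                "cleavage_site", "validated_by",
            ],
        )

    def interactions_table(self) -> pd.DataFrame:
        rows = [
            {
                "phasirna": i.phasirna.name,
                "sequence": i.phasirna.rna_sequence,
                "target": i.target_id,
                "miru_start": i.miru_start,
                "miru_end": i.miru_end,
                "score": i.score,
                "cut_site": i.predicted_cut,
                "validated": i.validated,
                "validated_by": ";".join(i.validating_libraries),
            }
            for i in self.interactions
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "phasirna", "sequence", "target", "miru_start", "miru_end",
                "score", "cut_site", "validated", "validated_by",
            ],
        )

    def dcl_table(self) -> pd.DataFrame:
        rows = [
            {
                "locus": c.locus_id,
                "k": c.k,
                "wt_rpm": c.wt_rpm,
                "mutant_rpm": c.mutant_rpm,
                "fold": c.fold,
                "dependent": c.dependent,
            }
            for c in self.dcl_calls
        ]
        return pd.DataFrame(
            rows, columns=["locus", "k", "wt_rpm", "mutant_rpm", "fold", "dependent"]
        )


def discover(
    transcripts: list[SequenceRecord],
    srna_libraries: list[SmallRNALibrary],
    degradome_libraries: list[SmallRNALibrary],
    known_mirnas: list[SequenceRecord] = (),
    params: Mapping | None = None,
) -> DiscoveryResult:
    """Run the PHAS discovery screen on in-memory objects."""
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)

    srna_libraries = [normalize_rpm(lib) for lib in srna_libraries]
    degradome_libraries = [normalize_rpm(lib) for lib in degradome_libraries]

    profiles: dict[tuple[str, str], deg.DegradomeProfile] = {}
    for lib in degradome_libraries:
        for t in transcripts:
            profiles[(lib.name, t.id)] = deg.build_profile(lib, t)

    loci: list[DiscoveredLocus] = []
    all_regions: list[CandidateRegion] = []
    seen_loci: set[tuple] = set()
    for lib in srna_libraries:
        placements = map_reads(lib, transcripts)
        by_transcript: dict[str, list[ReadPlacement]] = {}
        for pl in placements:
            by_transcript.setdefault(pl.transcript_id, []).append(pl)
        for transcript in transcripts:
            t_placements = by_transcript.get(transcript.id, [])
            for k in p["k_values"]:
                regions = find_candidate_regions(
                    t_placements, transcript, k, min_duplexes=p["min_duplexes"]
                )
                all_regions.extend(regions)
                for region in regions:
                    profile = score_profile(
                        t_placements,
                        region.anchor,
                        k,
                        (region.region_start, region.region_end),
                    )
                    if not profile:
                        continue
                    max_score = region_max_score(profile)
                    if not max_score > p["score_threshold"]:
                        continue
                    # degradome signature inside the production region
                    signals = []
                    for dlib in degradome_libraries:
                        prof = profiles[(dlib.name, transcript.id)]
                        for sig in deg.detect_cleavage(
                            prof,
                            (
                                region.region_start - p["flank_tolerance"],
                                region.region_end,
                            ),
                            p["min_rpm"],
                            p["min_dominance"],
                        ):
                            if deg.flank_check(
                                sig.position, region, p["flank_tolerance"]
                            ):
                                signals.append(sig)
                    if not signals:
                        continue
                    triggers = find_trigger(
                        lib,
                        transcript,
                        region,
                        known_mirnas=known_mirnas,
                        max_score=p["max_score"],
                        flank_tolerance=p["flank_tolerance"],
                    )
                    validated_trigger = None
                    for cand in triggers:
                        cand = validate_trigger(
                            cand,
                            [
                                profiles[(d.name, transcript.id)]
                                for d in degradome_libraries
                            ],
                            p["min_rpm"],
                            p["min_dominance"],
                            jitter=p["cleavage_jitter"],
                        )
                        if cand.validated:
                            validated_trigger = cand
                            break
                    if validated_trigger is None:
                        continue
                    key = (
                        transcript.id,
                        k,
                        region.anchor % k,
                        region.region_start,
                        region.region_end,
                    )
                    if key in seen_loci:
                        continue
                    seen_loci.add(key)
                    loci.append(
                        DiscoveredLocus(
                            region=region,
                            max_score=max_score,
                            cleavage_signals=signals,
                            trigger=validated_trigger,
                            library_name=lib.name,
                            placements=t_placements,
                        )
                    )

    result = DiscoveryResult(
        loci=loci, candidate_regions=all_regions, profiles=profiles
    )

    # phasiRNA enumeration and target validation for validated 21-nt loci
    transcript_by_id = {t.id: t for t in transcripts}
    lib_by_name = {lib.name: lib for lib in srna_libraries}
    for locus in loci:
        if locus.region.k != 21:
            continue
        transcript = transcript_by_id[locus.region.transcript_id]
        anchor = (
            locus.trigger.predicted_cleavage
            if locus.trigger is not None
            else locus.region.anchor
        )
        phasirnas = enumerate_phasirnas(
            transcript,
            anchor,
            locus.region.k,
            library=lib_by_name[locus.library_name],
            arm="3'",
            region_end=locus.region.region_end,
        )
        expressed = [
            ph for ph in phasirnas if ph.rpm > p["min_phasirna_rpm"]
        ]
        result.phasirnas.extend(expressed)
        for ph in expressed:
            targets = [
                t for t in transcripts if t.id != locus.region.transcript_id
            ]
            interactions = predict_targets(ph, targets, max_score=p["max_score"])
            interactions = validate_interactions(
                interactions,
                [
                    profiles[(d.name, t.id)]
                    for d in degradome_libraries
                    for t in transcripts
                    if (d.name, t.id) in profiles
                ],
                p["min_rpm"],
                p["min_dominance"],
            )
            result.interactions.extend(interactions)
    return result


def add_dcl_calls(
    result: DiscoveryResult,
    transcripts: list[SequenceRecord],
    wt: SmallRNALibrary,
    mutants: Mapping[int, SmallRNALibrary],
    threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> None:
    """Attach DCL-dependence calls for loci whose k has a mutant library."""
    transcript_by_id = {t.id: t for t in transcripts}
    wt = normalize_rpm(wt)
    mutants = {k: normalize_rpm(lib) for k, lib in mutants.items()}
    for locus in result.loci:
        k = locus.region.k
        if k not in mutants:
            continue
        result.dcl_calls.append(
            call_dependence(
                locus.region,
                wt,
                mutants[k],
                transcript_by_id[locus.region.transcript_id],
                threshold=threshold,
            )
        )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping")
    return config


def _require(config: Mapping, key: str) -> object:
    if key not in config:
        raise ConfigurationError(f"config is missing required key {key!r}")
    return config[key]


def _load_libraries(entries, base: Path) -> list[SmallRNALibrary]:
    libs = []
    for entry in entries:
        if isinstance(entry, str):
            entry = {"path": entry}
        path = base / entry["path"]
        libs.append(
            read_srna_library(
                path,
                format=entry.get("format", "tsv"),
                name=entry.get("name"),
            )
        )
    return libs


def _write_log(outdir: Path, params: Mapping, lines: list[str]) -> None:
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write("# thresholds\n")
        for key in sorted(params):
            fh.write(f"{key} = {params[key]}\n")
        fh.write("# run\n")
        for line in lines:
            fh.write(line + "\n")
            print(line, file=sys.stderr)


def run_phas_discovery(config: Mapping | str | Path, outdir: str | Path) -> DiscoveryResult:
    """File-based discovery run; writes report tables under ``outdir``."""
    if not isinstance(config, Mapping):
        config_path = Path(config)
        base = config_path.parent
        config = load_config(config_path)
    else:
        base = Path(config.get("base_dir", "."))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))

    transcripts = read_fasta(base / _require(config, "transcripts"))
    srna_libs = _load_libraries(_require(config, "srna_libraries"), base)
    deg_libs = _load_libraries(_require(config, "degradome_libraries"), base)
    known = (
        read_fasta(base / config["known_mirnas"])
        if config.get("known_mirnas")
        else []
    )

    result = discover(transcripts, srna_libs, deg_libs, known, params)

    if config.get("mutant_libraries"):
        mutants = {
            int(k): _load_libraries([entry], base)[0]
            for k, entry in config["mutant_libraries"].items()
        }
        add_dcl_calls(
            result, transcripts, srna_libs[0], mutants, params["fold_threshold"]
        )

    result.loci_table().to_csv(outdir / "phas_loci.tsv", sep="\t", index=False)
    result.interactions_table().to_csv(
        outdir / "interactions.tsv", sep="\t", index=False
    )
    build_network_table(result.interactions).to_csv(
        outdir / "network_edges.tsv", sep="\t", index=False
    )
    result.dcl_table().to_csv(outdir / "dcl_calls.tsv", sep="\t", index=False)

    region_rows = [
        {
            "transcript_id": r.transcript_id,
            "k": r.k,
            "anchor": r.anchor,
            "start": r.region_start,
            "end": r.region_end,
            "n_occupied_tandem": r.n_occupied_tandem,
        }
        for r in result.candidate_regions
    ]
    pd.DataFrame(
        region_rows,
        columns=["transcript_id", "k", "anchor", "start", "end", "n_occupied_tandem"],
    ).to_csv(outdir / "candidate_regions.tsv", sep="\t", index=False)

    profile_rows = [
        {"library": lib, "transcript_id": tid, "position": pos, "rpm": rpm}
        for (lib, tid), prof in result.profiles.items()
        for pos, rpm in sorted(prof.signal.items())
    ]
    pd.DataFrame(
        profile_rows, columns=["library", "transcript_id", "position", "rpm"]
    ).to_csv(outdir / "degradome_profiles.tsv", sep="\t", index=False)

    _write_log(
        outdir,
        params,
        [
            f"transcripts: {len(transcripts)}",
            f"candidate regions: {len(result.candidate_regions)}",
            f"validated loci: {len(result.loci)}",
            f"expressed phasiRNAs: {len(result.phasirnas)}",
            f"validated interactions: "
            f"{sum(1 for i in result.interactions if i.validated)}",
            f"dcl calls: {len(result.dcl_calls)}",
        ],
    )
    return result


def run_rddm(config: Mapping | str | Path, outdir: str | Path) -> dict:
    """24-nt phasiRNA promoter targeting + methylation/expression report."""
    if not isinstance(config, Mapping):
        config_path = Path(config)
        base = config_path.parent
        config = load_config(config_path)
    else:
        base = Path(config.get("base_dir", "."))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    promoters = read_fasta(base / _require(config, "promoters"), kind="promoter")
    cdnas = read_fasta(base / _require(config, "cdnas"))
    cdna_by_id = {c.id: c for c in cdnas}
    promoter_target = dict(config.get("promoter_target_map", {}))

    phasirnas = read_phasirna_table(base / _require(config, "phasirnas"))
    hits = rddm_mod.find_promoter_hits(phasirnas, promoters)
    hits_df = pd.DataFrame(
        [
            {
                "phasirna": h.phasirna_name,
                "sequence": h.phasirna_sequence,
                "promoter": h.promoter_id,
                "start": h.start,
                "end": h.end,
                "orientation": h.orientation,
                "target_gene": promoter_target.get(h.promoter_id, ""),
            }
            for h in hits
        ],
        columns=[
            "phasirna", "sequence", "promoter", "start", "end",
            "orientation", "target_gene",
        ],
    )
    hits_df.to_csv(outdir / "promoter_hits.tsv", sep="\t", index=False)

    bisulfite = {
        tissue: read_srna_library(base / path, name=f"bisulfite_{tissue}")
        for tissue, path in _require(config, "bisulfite").items()
    }
    rnaseq = {
        tissue: normalize_rpm(
            read_srna_library(base / path, name=f"rnaseq_{tissue}")
        )
        for tissue, path in _require(config, "rnaseq").items()
    }

    target_promoters = sorted({h.promoter_id for h in hits})
    promoter_by_id = {p.id: p for p in promoters}
    profiles: dict[tuple[str, str], rddm_mod.MethylationProfile] = {}
    expression: dict[tuple[str, str], float] = {}
    for tissue, lib in bisulfite.items():
        mapped = rddm_mod.map_bisulfite_reads(lib, promoters)
        for pid in target_promoters:
            profile = rddm_mod.methylation_profile(
                mapped[pid], lib.total_count, promoter_by_id[pid], lib.name
            )
            profiles[(tissue, pid)] = profile
            profile.to_frame().to_csv(
                outdir / f"methylation_{tissue}_{pid}.tsv", sep="\t", index=False
            )
    for tissue, lib in rnaseq.items():
        for pid in target_promoters:
            gene = promoter_target.get(pid)
            if gene and gene in cdna_by_id:
                expression[(tissue, pid)] = rddm_mod.expression_rpm(
                    lib, cdna_by_id[gene]
                )

    expressing = config.get("expressing_tissue")
    other = config.get("other_tissue")
    comparisons = []
    if expressing in bisulfite and other in bisulfite:
        for pid in target_promoters:
            comparisons.append(
                rddm_mod.compare_tissues(
                    profiles[(expressing, pid)],
                    profiles[(other, pid)],
                    expression.get((expressing, pid), 0.0),
                    expression.get((other, pid), 0.0),
                    expressing,
                    other,
                )
            )
    else:
        print(
            "warning: both tissues not available; RdDM comparison skipped",
            file=sys.stderr,
        )

    comp_df = pd.DataFrame(
        [
            {
                "promoter": c.promoter_id,
                "expressing_tissue": c.expressing_tissue,
                "other_tissue": c.other_tissue,
                "chh_expressing": c.chh_expressing,
                "chh_other": c.chh_other,
                "expression_expressing": c.expression_expressing,
                "expression_other": c.expression_other,
                "consistent_rddm": c.consistent,
            }
            for c in comparisons
        ],
        columns=[
            "promoter", "expressing_tissue", "other_tissue", "chh_expressing",
            "chh_other", "expression_expressing", "expression_other",
            "consistent_rddm",
        ],
    )
    comp_df.to_csv(outdir / "rddm_consistency.tsv", sep="\t", index=False)

    expr_df = pd.DataFrame(
        [
            {"tissue": tissue, "promoter": pid, "target_rpm": rpm}
            for (tissue, pid), rpm in sorted(expression.items())
        ],
        columns=["tissue", "promoter", "target_rpm"],
    )
    expr_df.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    return {
        "hits": hits,
        "profiles": profiles,
        "expression": expression,
        "comparisons": comparisons,
    }


def run_targets(config: Mapping | str | Path, outdir: str | Path) -> pd.DataFrame:
    """Target prediction/validation for an existing phasiRNA table."""
    if not isinstance(config, Mapping):
        config_path = Path(config)
        base = config_path.parent
        config = load_config(config_path)
    else:
        base = Path(config.get("base_dir", "."))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    transcripts = read_fasta(base / _require(config, "transcripts"))
    phasirnas = read_phasirna_table(base / _require(config, "phasirnas"))
    deg_libs = [
        normalize_rpm(lib)
        for lib in _load_libraries(_require(config, "degradome_libraries"), base)
    ]
    profiles = [
        deg.build_profile(lib, t) for lib in deg_libs for t in transcripts
    ]
    interactions: list[TargetInteraction] = []
    for ph in phasirnas:
        found = predict_targets(ph, transcripts, max_score=params["max_score"])
        interactions.extend(
            validate_interactions(
                found, profiles, params["min_rpm"], params["min_dominance"]
            )
        )
    df = DiscoveryResult([], [], {}, interactions=interactions).interactions_table()
    df.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    build_network_table(interactions).to_csv(
        outdir / "network_edges.tsv", sep="\t", index=False
    )
    return df


def run_dcl(config: Mapping | str | Path, outdir: str | Path) -> pd.DataFrame:
    """DCL-dependence calls for regions listed in a candidate-region TSV."""
    if not isinstance(config, Mapping):
        config_path = Path(config)
        base = config_path.parent
        config = load_config(config_path)
    else:
        base = Path(config.get("base_dir", "."))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    transcripts = read_fasta(base / _require(config, "transcripts"))
    transcript_by_id = {t.id: t for t in transcripts}
    wt = normalize_rpm(
        _load_libraries([_require(config, "wt_library")], base)[0]
    )
    mutants = {
        int(k): normalize_rpm(_load_libraries([entry], base)[0])
        for k, entry in _require(config, "mutant_libraries").items()
    }
    regions_df = pd.read_csv(base / _require(config, "regions"), sep="\t")
    calls = []
    for _, row in regions_df.iterrows():
        k = int(row["k"])
        if k not in mutants:
            continue
        region = CandidateRegion(
            transcript_id=str(row["transcript_id"]),
            k=k,
            anchor=int(row["anchor"]),
            region_start=int(row["start"]),
            region_end=int(row["end"]),
        )
        calls.append(
            call_dependence(
                region,
                wt,
                mutants[k],
                transcript_by_id[region.transcript_id],
                threshold=params["fold_threshold"],
            )
        )
    df = DiscoveryResult([], [], {}, dcl_calls=calls).dcl_table()
    df.to_csv(outdir / "dcl_calls.tsv", sep="\t", index=False)
    return df


def read_phasirna_table(path: str | Path) -> list[PhasiRNA]:
    """Read a (name, sequence) TSV of phasiRNAs, parsing the D-names."""
    from .seq_io import to_dna

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        fields = parse_phasirna_name(str(row["name"]))
        out.append(
            PhasiRNA(
                locus_id=fields["locus_id"],
                anchor=fields["anchor"],
                k=fields["k"],
                duplex_index=fields["duplex_index"],
                strand=fields["strand"],
                arm=fields["arm"],
                sequence=to_dna(str(row["sequence"])),
            )
        )
    return out
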