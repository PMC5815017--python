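"""File formats: FASTA genomes, BED fragment/insertion lists, bedGraph
tracks, CSV titrations, and the YAML-driven generator entry point.

BED records are 0-based half-open per the BED standard; the strand field
is ignored for fragments (they are double-stranded molecules). Fragments
that wrap the origin of a circular genome are written unwrapped (end >
genome length) so that start/length round-trip exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from parbseq import chip, coverage, genome as genome_mod, idap, simulate, spr, tnseq

DEFAULT_CHROM = "chr"


# -- FASTA ------------------------------------------------------------------


def write_fasta(genome: genome_mod.Genome, path, name: str = DEFAULT_CHROM) -> None:
    record = SeqRecord(Seq(genome.sequence), id=name, description="")
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path, circular: bool = True) -> genome_mod.Genome:
    """Load the first FASTA record as a genome (no site annotations)."""
    record = next(SeqIO.parse(str(path), "fasta"))
    seq = str(record.seq).upper()
    spec = genome_mod.GenomeSpec(length=len(seq), circular=circular, sequence=seq)
    return genome_mod.Genome(spec=spec)


# -- BED fragments ----------------------------------------------------------


def write_fragments_bed(
    fragments: Sequence[simulate.FragmentRecord], path, chrom: str = DEFAULT_CHROM
) -> None:
    with open(path, "w") as fh:
        for i, frag in enumerate(fragments):
            fh.write(f"{chrom}\t{frag.start}\t{frag.start + frag.length}\t{frag.source}_{i}\t0\n")


def read_fragments_bed(path, source: str = "chip") -> simulate.FragmentSample:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            start, end = int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else source
            records.append(
                simulate.FragmentRecord(start=start, length=end - start, source=name.rsplit("_", 1)[0])
            )
    return simulate.FragmentSample(records)


# -- BED insertions ---------------------------------------------------------


def write_insertions_bed(
    library: simulate.InsertionLibrary, path, chrom: str = DEFAULT_CHROM
) -> None:
    """score column = per-position read count."""
    with open(path, "w") as fh:
        for pos, cnt in zip(library.positions, library.counts):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{library.label}\t{cnt}\n")


def read_insertions_bed(path, label: Optional[str] = None) -> simulate.InsertionLibrary:
    positions, counts, labels = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            positions.append(int(fields[1]))
            labels.append(fields[3] if len(fields) > 3 else "")
            counts.append(int(fields[4]) if len(fields) > 4 else 1)
    return simulate.InsertionLibrary(
        positions=np.array(positions, dtype=np.int64),
        counts=np.array(counts, dtype=np.int64),
        label=label or (labels[0] if labels else "parS_plus"),
    )


# -- bedGraph tracks --------------------------------------------------------


def write_bedgraph(track: coverage.CoverageTrack, path, chrom: str = DEFAULT_CHROM) -> None:
    """4-column bedGraph with consecutive equal values run-length collapsed.

    Positions are in bp; for binned tracks each entry spans ``bin_size``.
    """
    values = track.values
    step = track.bin_size
    with open(path, "w") as fh:
        if values.size == 0:
            return
        edges = np.nonzero(np.diff(values))[0] + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [values.size]])
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{s * step}\t{e * step}\t{values[s]:.6g}\n")


def read_bedgraph(path, bin_size: int = 1, units: str = coverage.RAW) -> coverage.CoverageTrack:
    starts, ends, vals = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            starts.append(int(fields[1]))
            ends.append(int(fields[2]))
            vals.append(float(fields[3]))
    if not starts:
        return coverage.CoverageTrack(values=np.zeros(0), units=units, bin_size=bin_size)
    n = ends[-1] // bin_size
    values = np.zeros(n)
    for s, e, v in zip(starts, ends, vals):
        values[s // bin_size : e // bin_size] = v
    return coverage.CoverageTrack(values=values, units=units, bin_size=bin_size)


# -- binding calls ----------------------------------------------------------


def write_calls_bed(calls: Sequence[idap.BindingCall], path, chrom: str = DEFAULT_CHROM) -> None:
    """BED6: name = called sequence (or 'call_<i>'), score = height."""
    with open(path, "w") as fh:
        for i, call in enumerate(calls):
            name = call.sequence or f"call_{i}"
            fh.write(
                f"{chrom}\t{call.site_start}\t{call.site_start + call.length}\t"
                f"{name}\t{call.height:.6g}\t.\n"
            )


def write_calls_tsv(calls: Sequence[idap.BindingCall], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            [
                "site_start",
                "site_end",
                "length",
                "upper_summit",
                "lower_summit",
                "height",
                "sequence",
                "palindrome_hits",
            ]
        )
        for call in calls:
            writer.writerow(
                [
                    call.site_start,
                    call.site_end,
                    call.length,
                    call.upper_summit,
                    call.lower_summit,
                    f"{call.height:.6g}",
                    call.sequence or "",
                    "" if call.palindrome_hits is None else call.palindrome_hits,
                ]
            )


def write_zones_bed(zones: Sequence[tnseq.Zone], path, chrom: str = DEFAULT_CHROM) -> None:
    with open(path, "w") as fh:
        for zone in zones:
            fh.write(
                f"{chrom}\t{zone.start}\t{zone.end}\t{zone.kind}\t"
                f"{zone.mean_log10_ratio:.4f}\n"
            )


def write_regions_bed(regions: Sequence[chip.EnrichedRegion], path, chrom: str = DEFAULT_CHROM) -> None:
    with open(path, "w") as fh:
        for region in regions:
            fh.write(
                f"{chrom}\t{region.start}\t{region.end}\tregion\t{region.max_signal:.6g}\n"
            )


# -- SPR titrations ---------------------------------------------------------


def read_titrations_csv(path) -> dict[str, spr.TitrationSeries]:
    """CSV columns: concentration_nM, response_RU [, series_label]."""
    groups: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            label = row.get("series_label", "") or ""
            groups.setdefault(label, []).append(
                (float(row["concentration_nM"]), float(row["response_RU"]))
            )
    out = {}
    for label, points in groups.items():
        conc, resp = zip(*points)
        out[label] = spr.TitrationSeries(
            concentrations=np.array(conc), responses=np.array(resp), label=label
        )
    return out


def write_titration_csv(series: spr.TitrationSeries, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["concentration_nM", "response_RU", "series_label"])
        for c, r in zip(series.concentrations, series.responses):
            writer.writerow([f"{c:g}", f"{r:.6g}", series.label])


def write_kdfits_csv(fits: Mapping[str, spr.KdFit], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["series_label", "kd_nM", "se_kd", "rmax", "rss", "converged"])
        for label, fit in fits.items():
            writer.writerow(
                [
                    label,
                    f"{fit.kd:.6g}",
                    f"{fit.standard_error_kd:.6g}",
                    f"{fit.rmax:.6g}",
                    f"{fit.residual_sum_of_squares:.6g}",
                    fit.converged,
                ]
            )


# -- YAML-driven generation -------------------------------------------------


def run_config(config_path, outdir) -> dict[str, Path]:
    """Generate a synthetic data set from a YAML configuration.

    The configuration must carry an explicit integer ``seed``; each output
    section draws from an independent stream derived from it. Recognised
    sections (all optional except ``genome``): ``chip`` (n, optional
    spreading/amplitude/background), ``input`` (n), ``idap`` (n,
    protein_conc_nM, background_prob), ``idap_control`` (n), ``tn_plus`` /
    ``tn_minus`` (n, optional plateau center/width/level), ``spr`` (list
    of {label, kd_nM, rmax, noise_sd}). Returns a mapping of section name
    to the written file path.
    """
    cfg = yaml.safe_load(Path(config_path).read_text())
    if "seed" not in cfg:
        raise ValueError("config must set an explicit integer seed")
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    gcfg = cfg.get("genome", {})
    genome = genome_mod.default_genome(
        length=int(gcfg.get("length", 1_000_000)),
        cluster_center=int(gcfg.get("cluster_center", 7500)),
        seed=seed,
    )
    fasta = outdir / "genome.fasta"
    write_fasta(genome, fasta)
    written["genome"] = fasta

    spreading = int(cfg.get("chip", {}).get("spreading_extent_per_side", 2992))
    amplitude = float(cfg.get("chip", {}).get("amplitude", 1.0))
    background = float(cfg.get("chip", {}).get("background", 0.0))
    if "chip" in cfg:
        occ = simulate.simulate_occupancy(
            genome, genome.sites, spreading, [amplitude] * len(genome.sites), background
        )
        frags = simulate.simulate_chip_fragments(
            occ, int(cfg["chip"]["n"]), seed=seed + 1
        )
        path = outdir / "chip.bed"
        write_fragments_bed(frags, path)
        written["chip"] = path
    if "input" in cfg:
        occ = simulate.OccupancyProfile(values=np.ones(genome.length))
        frags = simulate.simulate_chip_fragments(
            occ, int(cfg["input"]["n"]), seed=seed + 2, source="input"
        )
        path = outdir / "input.bed"
        write_fragments_bed(frags, path)
        written["input"] = path
    if "idap" in cfg:
        frags = simulate.simulate_idap_fragments(
            genome,
            protein_conc=float(cfg["idap"].get("protein_conc_nM", 320.0)),
            n=int(cfg["idap"]["n"]),
            seed=seed + 3,
            background_prob=float(cfg["idap"].get("background_prob", 0.001)),
        )
        path = outdir / "idap.bed"
        write_fragments_bed(frags, path)
        written["idap"] = path
    if "idap_control" in cfg:
        frags = simulate.simulate_idap_fragments(
            genome,
            sites=[],
            protein_conc=320.0,
            n=int(cfg["idap_control"]["n"]),
            seed=seed + 4,
            background_prob=float(cfg["idap_control"].get("background_prob", 0.001)),
            source="control",
        )
        path = outdir / "idap_control.bed"
        write_fragments_bed(frags, path)
        written["idap_control"] = path
    for section, label, offset in (("tn_plus", "parS_plus", 5), ("tn_minus", "parS_minus", 6)):
        if section not in cfg:
            continue
        scfg = cfg[section]
        weights = np.ones(genome.length)
        if "plateau_width" in scfg:
            center = int(scfg.get("plateau_center", genome.spec.native_cluster_position))
            width = int(scfg["plateau_width"])
            level = float(scfg.get("plateau_level", 10.0))
            idx = np.arange(center - width // 2, center + width - width // 2) % genome.length
            weights[idx] = level
        library = simulate.simulate_tn_library(
            simulate.FitnessLandscape(relative_fitness=weights),
            int(scfg["n"]),
            seed=seed + offset,
            label=label,
        )
        path = outdir / f"{section}.bed"
        write_insertions_bed(library, path)
        written[section] = path
    if "spr" in cfg:
        path = outdir / "titrations.csv"
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["concentration_nM", "response_RU", "series_label"])
            for i, item in enumerate(cfg["spr"]):
                series = simulate.simulate_spr_titration(
                    kd=float(item["kd_nM"]),
                    rmax=float(item.get("rmax", 100.0)),
                    noise_sd=float(item.get("noise_sd", 0.0)),
                    seed=seed + 10 + i,
                    label=str(item.get("label", f"series_{i}")),
                )
                for c, r in zip(series.concentrations, series.responses):
                    writer.writerow([f"{c:g}", f"{r:.6g}", series.label])
        written["spr"] = path
    return written
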