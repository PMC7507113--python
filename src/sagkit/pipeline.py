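"""End-to-end analysis: simulate a community, run every stage, write TSVs.

One config + seed drives simulation, coding-density/table selection, 16S
detection and classification, co-sort flagging with chi-square
decomposition, energy-metabolism profiling, COG ordination, and the
cohort report. Running twice with the same config and seed produces
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .community import Community, simulate_community
from .cosort import (ChiSquareDecomposition, chisq_decomposition,
                     flag_cosorts, marker_census)
from .genes import coding_density
from .ordination import build_cog_matrix, filter_genomes, group_separation, ordinate
from .report import (boxstats, cosort_count_table, cumulative_complete_genomes,
                     pairwise_diameter_tests, pct, plate_abundance)
from .ssu import classify_ssu, detect_ssu, refdb_from_panel
from .energy import genome_energy_profile

__all__ = ["PipelineResult", "run_pipeline", "analyze_community"]


@dataclass
class PipelineResult:
    community: Community
    density: pd.DataFrame
    ssu: pd.DataFrame
    census: pd.DataFrame
    flags: pd.DataFrame
    chisq: dict[str, ChiSquareDecomposition]
    energy: pd.DataFrame
    cog_matrix: pd.DataFrame
    coordinates: pd.DataFrame
    group_tests: pd.DataFrame
    summary: pd.DataFrame
    box: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def analyze_community(
    community: Community,
    min_orf_len: int = 90,
    min_ssu_detect_len: int = 1000,
    min_ssu_tree_len: int = 1200,
    conf_floor: float = 80.0,
    contam_threshold: float = 10.0,
    min_completeness: float = 30.0,
    n_axes: int = 2,
    seed: int = 0,
) -> PipelineResult:
    """Run every analysis stage over an in-memory community."""
    refdb = refdb_from_panel(community.phylum_refs, seed=seed)
    panel = community.phylum_refs

    dens_rows, ssu_rows, census_rows, flag_rows, energy_rows = [], [], [], [], []
    ann_all: list[dict] = []
    meta: dict[str, dict] = {}
    flags_list = []
    for sag in community.sags:
        group = sag.truth["source_phyla"][0]
        r = coding_density(sag.contigs, genome_id=sag.sag_id,
                           min_orf_len=min_orf_len)
        dens_rows.append(dict(
            sag_id=sag.sag_id, total_cds_11=r.total_cds_11,
            total_cds_25=r.total_cds_25, chosen_table=r.chosen_table,
            coding_density=round(r.coding_density, 6),
            density_gt_one=r.density_gt_one,
        ))
        hits = detect_ssu(sag.contigs, panel, min_len=min_ssu_detect_len,
                          sag_id=sag.sag_id)
        classifications = []
        for h in hits:
            c = classify_ssu(h.sequence, refdb, seed=seed, hit=h)
            classifications.append(c)
            ssu_rows.append(dict(
                sag_id=sag.sag_id, contig_id=h.contig_id, start=h.start,
                end=h.end, strand=h.strand, length_nt=h.length_nt,
                phylum=c.phylum, confidence=c.confidence,
            ))
        markers = [r_["marker_id"] for r_ in sag.annotations
                   if r_.get("marker_id")]
        census = marker_census(markers, genome_id=sag.sag_id)
        census_rows.append(dict(
            sag_id=sag.sag_id, found=census.found,
            duplicated=census.duplicated,
            completeness_pct=round(census.completeness_pct, 3),
            contamination_pct=round(census.contamination_pct, 3),
        ))
        fl = flag_cosorts(census, classifications,
                          min_ssu_len=min_ssu_detect_len,
                          conf_floor=conf_floor,
                          contam_threshold=contam_threshold, group=group)
        flags_list.append(fl)
        flag_rows.append(dict(
            sag_id=sag.sag_id, group=group, by_markers=fl.by_markers,
            by_ssu=fl.by_ssu, admixture_truth=sag.truth["admixture"],
        ))
        ep = genome_energy_profile(sag.annotations, sag.aa_seqs,
                                   genome_id=sag.sag_id)
        energy_rows.append(dict(
            sag_id=sag.sag_id, group=group,
            **{f"complex_{cx}": n for cx, n in ep.complex_counts.items()},
            n_complexes=len(ep.complexes_present),
            complete_etc=ep.complete_etc,
            n_o2red=len(ep.o2red_hits),
            ec1_fraction=round(ep.ec1_fraction, 4),
        ))
        ann_all.extend(sag.annotations)
        max_ssu = max((h.length_nt for h in hits), default=0)
        meta[sag.sag_id] = dict(group=group,
                                completeness_pct=census.completeness_pct,
                                ssu_len=max_ssu)

    density = pd.DataFrame(dens_rows)
    ssu_df = pd.DataFrame(ssu_rows, columns=[
        "sag_id", "contig_id", "start", "end", "strand", "length_nt",
        "phylum", "confidence"])
    census_df = pd.DataFrame(census_rows)
    flags_df = pd.DataFrame(flag_rows)
    energy_df = pd.DataFrame(energy_rows)

    chisq: dict[str, ChiSquareDecomposition] = {}
    for det in ("by_markers", "by_ssu"):
        tab = cosort_count_table(flags_list, detector=det)
        if (tab.sum(axis=1) > 0).all() and (tab.sum(axis=0) > 0).all() \
                and tab.shape[0] >= 2:
            chisq[det] = chisq_decomposition(
                tab.to_numpy(), row_labels=list(tab.index),
                col_labels=list(tab.columns))

    cog = build_cog_matrix(ann_all, metadata=meta)
    cog_f = filter_genomes(cog, min_completeness=min_completeness,
                           min_ssu_len=min_ssu_tree_len)
    coords_df = pd.DataFrame()
    tests_df = pd.DataFrame()
    if len(cog_f.values) >= 3:
        ordn = ordinate(cog_f, n_axes=n_axes)
        coords_df = pd.DataFrame(
            ordn.coordinates.round(6),
            index=ordn.genome_ids,
            columns=[f"PC{a + 1}" for a in range(n_axes)],
        )
        coords_df.insert(0, "group", [cog_f.group[g] for g in ordn.genome_ids])
        tests = group_separation(ordn.coordinates,
                                 [cog_f.group[g] for g in ordn.genome_ids],
                                 axis=0)
        tests_df = pd.DataFrame([
            dict(group_a=t.group_a, group_b=t.group_b, n_a=t.n_a, n_b=t.n_b,
                 statistic=t.statistic, p_value=t.p_value, method=t.method)
            for t in tests])

    sag_table = pd.DataFrame([
        dict(sag_id=s.sag_id, plate_id=s.plate_id,
             group=s.truth["source_phyla"][0], diameter_um=s.diameter_um)
        for s in community.sags])
    box_rows = []
    for g, sub in sag_table.groupby("group"):
        b = boxstats(sub["diameter_um"], group=g)
        box_rows.append(dict(group=g, n=b.n, median=b.median, q1=b.q1,
                             q3=b.q3, iqr=round(b.iqr, 6),
                             whisker_low=round(b.whisker_low, 6),
                             whisker_high=round(b.whisker_high, 6),
                             n_outliers=len(b.outliers)))
    box_df = pd.DataFrame(box_rows)

    total = len(community.sags)
    summary_rows = []
    for g, sub in flags_df.groupby("group"):
        comp = census_df.set_index("sag_id").loc[sub["sag_id"],
                                                 "completeness_pct"]
        summary_rows.append(dict(
            group=g,
            n_sags=len(sub),
            pct_of_total=pct(len(sub), total, 1),
            cosort_markers=int(sub["by_markers"].sum()),
            cosort_ssu=int(sub["by_ssu"].sum()),
            pct_cosort_markers=pct(int(sub["by_markers"].sum()), len(sub), 1),
            effective_complete_genomes=cumulative_complete_genomes(comp),
        ))
    summary_df = pd.DataFrame(summary_rows)

    plates = sorted(sag_table["plate_id"].unique())
    pa_rows = []
    for p in plates:
        fr = plate_abundance(sag_table, p, seed=seed)
        for g, v in fr.items():
            pa_rows.append(dict(plate_id=p, group=g, fraction=round(v, 6)))
    tables = {"plate_abundance": pd.DataFrame(pa_rows)}

    dia_tests, n_pairs, n_sig = pairwise_diameter_tests(
        sag_table.set_index("sag_id")["diameter_um"],
        sag_table.set_index("sag_id")["group"],
        focal_group="Patescibacteria"
        if (sag_table["group"] == "Patescibacteria").any()
        else sag_table["group"].iloc[0],
    )
    tables["diameter_tests"] = pd.DataFrame([
        dict(group_a=t.group_a, group_b=t.group_b, statistic=t.statistic,
             p_value=t.p_value, method=t.method) for t in dia_tests])

    return PipelineResult(
        community=community, density=density, ssu=ssu_df, census=census_df,
        flags=flags_df, chisq=chisq, energy=energy_df,
        cog_matrix=cog_f.values.round(6), coordinates=coords_df,
        group_tests=tests_df, summary=summary_df, box=box_df, tables=tables,
    )


def run_pipeline(
    outdir,
    seed: int = 0,
    n_taxa: int = 12,
    n_sags: int = 96,
    cosort_rate: float = 0.02,
    completeness_range: tuple[float, float] = (0.05, 0.61),
    write_contigs: bool = True,
    **analysis_kwargs,
) -> PipelineResult:
    """Simulate, analyze, and write all stage outputs under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    community = simulate_community(
        n_taxa=n_taxa, n_sags=n_sags, cosort_rate=cosort_rate,
        completeness_range=completeness_range, seed=seed)
    res = analyze_community(community, seed=seed, **analysis_kwargs)

    if write_contigs:
        contigs = {cid: s for sag in community.sags
                   for cid, s in sag.contigs.items()}
        io.write_fasta(contigs, out / "contigs.fasta")
    truth = pd.DataFrame([
        dict(sag_id=s.sag_id, plate_id=s.plate_id,
             taxon_ids=",".join(s.truth["source_taxa"]),
             completeness=",".join(f"{c:.4f}" for c in s.truth["completeness"]),
             admixture=s.truth["admixture"], diameter_um=s.diameter_um)
        for s in community.sags])
    io.write_tsv(truth, out / "truth.tsv")
    ann = pd.DataFrame([r for s in community.sags for r in s.annotations])
    io.write_tsv(ann, out / "annotations.tsv")
    io.write_tsv(res.density, out / "density.tsv")
    io.write_tsv(res.ssu, out / "ssu.tsv")
    io.write_tsv(res.census, out / "census.tsv")
    io.write_tsv(res.flags, out / "flags.tsv")
    for det, dec in res.chisq.items():
        rows = []
        for i, rl in enumerate(dec.row_labels):
            for j, cl in enumerate(dec.col_labels):
                rows.append(dict(
                    group=rl, status=cl,
                    observed=int(dec.observed[i, j]),
                    expected=round(dec.expected[i, j], 4),
                    residual=round(dec.residuals[i, j], 4),
                    pct_contribution=round(dec.pct_contribution[i, j], 4)))
        df = pd.DataFrame(rows)
        df.attrs["statistic"] = dec.statistic
        io.write_tsv(df, out / f"chisq_{det.removeprefix('by_')}.tsv")
    io.write_tsv(res.energy, out / "energy.tsv")
    io.write_tsv(res.cog_matrix.reset_index(names="genome_id"),
                 out / "cog_matrix.tsv")
    if len(res.coordinates):
        io.write_tsv(res.coordinates.reset_index(names="genome_id"),
                     out / "coordinates.tsv")
    if len(res.group_tests):
        io.write_tsv(res.group_tests, out / "group_tests.tsv")
    io.write_tsv(res.summary, out / "summary.tsv")
    io.write_tsv(res.box, out / "boxstats.tsv")
    for name, df in res.tables.items():
        io.write_tsv(df, out / f"{name}.tsv")
    io.write_config(community.config, out / "run_config.txt")
    return res
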