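"""Self-validation harnesses: oracle cross-checks and null calibration.

Each function here re-derives a pipeline result by an independent route —
full-sequence mutate-and-translate for the consequence caller, exhaustive
subset enumeration for the greedy structure selector, uniform-null
simulation for the permutation test — and measures agreement.  The test
suite asserts on these numbers and the acceptance script reports them; the
harness itself never shares a code path with what it checks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import Config, DEFAULT_CONFIG
from .fixtures import (
    FixtureSpec,
    genomic_offset_pairs,
    helix_ca,
    make_transcriptome,
    oracle_consequence,
    planted_counts,
)
from .ingest import GenomicVariant, annotate_consequence, complement
from .pathprox import LabeledSite, LabeledSiteSet, permutation_test
from .structsel import MapSegment, ResidueMap, StructureCandidate, candidate_utility, select_structures
from .xref import classify_xref

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# consequence caller vs full-CDS oracle
# ---------------------------------------------------------------------------


def consequence_oracle_trial(n_snvs: int = 1000, seed: int = 0) -> dict:
    """Random SNVs inside random toy CDS models: codon-level caller vs the
    brute-force mutate-and-translate oracle.  Returns counts of agreement
    in class and in the reported protein change."""
    rng = np.random.default_rng(seed)
    tr = make_transcriptome(FixtureSpec(seed=seed, n_genes=24))
    agree = 0
    class_counts: dict[str, int] = {}
    for _ in range(n_snvs):
        t = tr.transcripts[int(rng.integers(0, len(tr.transcripts)))]
        pairs = genomic_offset_pairs(t)
        gpos, offset = pairs[int(rng.integers(0, len(pairs)))]
        ref_cds = t.cds_sequence[offset]
        ref = ref_cds if t.strand == "+" else complement(ref_cds)
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        gv = GenomicVariant(chrom=t.chrom, pos=gpos, ref=ref, alt=alt)
        expected_class, expected_change = oracle_consequence(t, gv)
        got = annotate_consequence(gv, t)
        got_change = (
            (got.protein_variant.position, got.protein_variant.ref_aa, got.protein_variant.alt_aa)
            if got.protein_variant
            else None
        )
        if got.consequence_class == expected_class and got_change == expected_change:
            agree += 1
        class_counts[expected_class] = class_counts.get(expected_class, 0) + 1
    return {"n": n_snvs, "n_agree": agree, "by_class": class_counts}


# ---------------------------------------------------------------------------
# xref census conservation
# ---------------------------------------------------------------------------


def xref_census_trial(n_records: int = 40, seed: int = 0) -> dict:
    """Planted discrepancy-class mix vs the classifier's recovered census."""
    spec = FixtureSpec(seed=seed, n_genes=n_records)
    tr = make_transcriptome(spec)
    planted = planted_counts(spec.xref_class_mix, n_records)
    recovered: dict[str, int] = {k: 0 for k in planted}
    for row in tr.xref_rows:
        status = classify_xref(
            row["transcript_peptide"], row["curated_peptide"] or None
        )
        recovered[status] = recovered.get(status, 0) + 1
    return {
        "n_records": n_records,
        "planted": planted,
        "recovered": recovered,
        "exact": planted == recovered,
        "total_conserved": sum(recovered.values()) == n_records,
    }


# ---------------------------------------------------------------------------
# greedy structure selection vs exhaustive enumeration
# ---------------------------------------------------------------------------


def random_candidates(rng: np.random.Generator, n: int, protein_len: int = 100) -> list[StructureCandidate]:
    sources = ["PDB", "ALPHAFOLD", "SWISSMODEL", "MODBASE"]
    out = []
    for i in range(n):
        source = sources[int(rng.integers(0, 4))]
        if source == "PDB":
            method = ["xray", "cryoem", "nmr"][int(rng.integers(0, 3))]
            quality = float(rng.uniform(1.0, 4.5))
        else:
            method, quality = "model", float(rng.uniform(30, 95))
        length = int(rng.integers(10, protein_len + 1))
        start = int(rng.integers(1, protein_len - length + 2))
        oligo = 2 if rng.random() < 0.3 else 1
        segs = [
            MapSegment(chain=chr(ord("A") + c), transcript_start=start,
                       residue_start=start, seg_length=length)
            for c in range(oligo)
        ]
        out.append(
            StructureCandidate(
                structure_id=f"S{i + 1:02d}", source=source, method=method,
                quality=quality, oligomeric_state=oligo, coordinates_path="",
                residue_map=ResidueMap(f"S{i + 1:02d}", segs),
            )
        )
    return out


def sequence_total_utility(order, position: int, cfg: Config) -> float:
    sel, total = [], 0.0
    for c in order:
        total += candidate_utility(c, position, sel, cfg)
        sel.append(c)
    return total


def set_utility(subset, position: int, cfg: Config) -> float:
    """Order-free score of a structure set: the best sequential total over
    its permutations (only the redundancy term is order-sensitive)."""
    if not subset:
        return 0.0
    return max(
        sequence_total_utility(order, position, cfg)
        for order in itertools.permutations(subset)
    )


def brute_force_best(candidates, position: int, max_k: int, cfg: Config):
    """Exhaustive optimum over all subsets of size <= max_k."""
    best, arg = 0.0, ()
    for k in range(1, max_k + 1):
        for subset in itertools.combinations(candidates, k):
            s = set_utility(subset, position, cfg)
            if s > best:
                best, arg = s, subset
    return best, arg


def selection_oracle_trial(
    n_instances: int = 200,
    seed: int = 0,
    max_candidates: int = 8,
    max_k: int = 3,
    cfg: Config = DEFAULT_CONFIG,
) -> dict:
    """Greedy-vs-optimal comparison over random instances.

    Tracks the worst greedy/optimal utility ratio, how often the greedy set
    differs from an optimal one, and whether a covering structure was
    always selected when one existed.
    """
    rng = np.random.default_rng(seed)
    worst_ratio = 1.0
    n_suboptimal = 0
    coverage_violations = 0
    for _ in range(n_instances):
        n = int(rng.integers(1, max_candidates + 1))
        cands = random_candidates(rng, n)
        position = int(rng.integers(1, 101))
        k = int(rng.integers(1, max_k + 1))
        sel = select_structures(cands, position, max_k=k, cfg=cfg)
        greedy_total = set_utility(tuple(sel.selected), position, cfg)
        opt, opt_set = brute_force_best(cands, position, k, cfg)
        if opt > 0:
            ratio = greedy_total / opt
            worst_ratio = min(worst_ratio, ratio)
            if {c.structure_id for c in sel.selected} != {c.structure_id for c in opt_set} and greedy_total < opt - 1e-9:
                n_suboptimal += 1
        if any(c.covers(position) for c in cands) and not any(
            c.covers(position) for c in sel.selected
        ):
            coverage_violations += 1
    return {
        "n_instances": n_instances,
        "worst_ratio": worst_ratio,
        "n_suboptimal": n_suboptimal,
        "coverage_violations": coverage_violations,
        "guarantee": 1 - 1 / np.e,
    }


# ---------------------------------------------------------------------------
# permutation-test null calibration
# ---------------------------------------------------------------------------


def null_calibration_trial(
    n_cases: int = 2000,
    n_perm: int = 199,
    n_residues: int = 80,
    n_pathogenic: int = 8,
    n_benign: int = 8,
    seed: int = 0,
    cfg: Config = DEFAULT_CONFIG,
) -> dict:
    """Uniform-null calibration of the clustering permutation test.

    Each simulated case places both labeled site sets and the query
    uniformly on an ideal-helix chain — the null geometry — and runs the
    full test.  Under the null the p-values should be uniform; the trial
    reports the empirical type-I error at alpha = 0.05 and the KS statistic
    against the uniform distribution.
    """
    coords = helix_ca(n_residues, start_index=1)
    residues = list(range(1, n_residues + 1))
    ca = {("A", r): coords[i] for i, r in enumerate(residues)}
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_cases)
    for i in range(n_cases):
        picks = rng.choice(residues, size=n_pathogenic + n_benign + 1, replace=False)
        path_res = picks[:n_pathogenic]
        ben_res = picks[n_pathogenic:-1]
        query = int(picks[-1])
        sites = LabeledSiteSet(
            "null",
            [LabeledSite("A", int(r), tuple(ca[("A", int(r))]), "pathogenic") for r in path_res]
            + [LabeledSite("A", int(r), tuple(ca[("A", int(r))]), "benign") for r in ben_res],
        )
        res = permutation_test(
            ca[("A", query)], ("A", query), sites, ca,
            n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)), cfg=cfg,
        )
        pvals[i] = res.p_value
    alpha = 0.05
    type1 = float(np.mean(pvals <= alpha))
    lo, hi = stats.binom.ppf([0.005, 0.995], n_cases, alpha) / n_cases
    ks = float(stats.kstest(pvals, "uniform").statistic)
    ks_crit_1pct = 1.6276 / np.sqrt(n_cases)
    return {
        "n_cases": n_cases,
        "n_perm": n_perm,
        "type1_error": type1,
        "binom99_low": float(lo),
        "binom99_high": float(hi),
        "ks_stat": ks,
        "ks_crit_1pct": float(ks_crit_1pct),
        "p_values": pvals,
    }


def power_curve_trial(
    separations=(0.0, 8.0, 30.0),
    n_cases: int = 60,
    n_perm: int = 199,
    n_residues: int = 120,
    seed: int = 0,
    cfg: Config = DEFAULT_CONFIG,
) -> dict:
    """Median p-value of planted-cluster queries across a separation grid.

    Pathogenic sites are planted inside a tight cluster and the query is
    drawn from that same cluster; benign sites sit at least ``separation``
    away, so power should rise (median p fall) monotonically with
    separation.
    """
    from .fixtures import ClusterGeometry, plant_clusters

    coords = helix_ca(n_residues, start_index=1)
    ca = {("A", r): coords[r - 1] for r in range(1, n_residues + 1)}
    rng = np.random.default_rng(seed)
    medians = []
    for sep in separations:
        geom = ClusterGeometry(n_pathogenic=8, n_benign=8, cluster_radius=8.0, separation=sep)
        ps = []
        for _ in range(n_cases):
            rows, truth = plant_clusters("pw", ca, geom, seed=int(rng.integers(0, 2**31 - 1)))
            sites = LabeledSiteSet(
                "pw",
                [
                    LabeledSite(r["chain"], r["residue"], tuple(ca[(r["chain"], r["residue"])]), r["label"])
                    for r in rows
                ],
            )
            query = int(rng.choice(truth["pathogenic"]))
            res = permutation_test(
                ca[("A", query)], ("A", query), sites, ca,
                n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)), cfg=cfg,
            )
            ps.append(res.p_value)
        medians.append(float(np.median(ps)))
    return {"separations": list(separations), "median_p": medians}
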