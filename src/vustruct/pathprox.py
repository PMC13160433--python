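"""Spatial-clustering pathogenicity analysis with a permutation null.

The statistic asks whether a query variant's residue sits closer, in 3D, to
the constellation of known-pathogenic sites than to known-benign sites on
the same structure.  Proximity to a labeled set is the mean of a distance
kernel K(d) over the set's representative atoms (Cα), and the score is

    score(q) = proximity(q, pathogenic) − proximity(q, benign)

so positive scores mean a better fit to the pathogenic constellation.  The
default kernel is K(d) = 1/(1+d) with d the Euclidean Cα–Cα distance in Å;
an exponential alternative exp(-d/scale) is available via config.

Significance comes from a permutation null: both labeled site sets are
relocated onto residues drawn uniformly without replacement from the mapped
residues of the chain, the score recomputed each draw, and the p-value taken
with the +1 convention, p = (1 + #{null ≥ observed}) / (1 + n_perm).  The
query's own residue is excluded both from the observed site sets
(leave-one-out) and from the relocation pool, keeping observed and null
scores exchangeable — under a uniform null the p-value is then exactly
uniform on {1/(n+1), …, 1}.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import Config, DEFAULT_CONFIG

LABELS = ("pathogenic", "benign")


class PathProxError(Exception):
    pass


@dataclass(frozen=True)
class LabeledSite:
    chain: str
    residue_number: int
    coord: tuple[float, float, float]
    label: str  # pathogenic | benign


@dataclass
class LabeledSiteSet:
    """Pathogenic/benign labeled residues with Cα coordinates, one structure."""

    structure_id: str
    sites: list[LabeledSite]

    def __post_init__(self):
        for s in self.sites:
            if s.label not in LABELS:
                raise ValueError(f"unknown label {s.label!r}")
            if not np.all(np.isfinite(s.coord)):
                raise ValueError(f"non-finite coordinate on {s.chain}{s.residue_number}")
        # collapse duplicate residue addresses, first occurrence wins
        seen: set[tuple[str, int]] = set()
        unique = []
        for s in self.sites:
            key = (s.chain, s.residue_number)
            if key not in seen:
                seen.add(key)
                unique.append(s)
        self.sites = unique

    def coords(self, label: str, exclude: tuple[str, int] | None = None) -> np.ndarray:
        pts = [
            s.coord
            for s in self.sites
            if s.label == label and (exclude is None or (s.chain, s.residue_number) != exclude)
        ]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    def swap_labels(self) -> "LabeledSiteSet":
        flip = {"pathogenic": "benign", "benign": "pathogenic"}
        return LabeledSiteSet(
            self.structure_id,
            [LabeledSite(s.chain, s.residue_number, s.coord, flip[s.label]) for s in self.sites],
        )


def load_sites_csv(path: str | Path, structure_id: str | None = None) -> LabeledSiteSet:
    """Read labeled sites (CSV ``structure_id,chain,residue,label``); Cα
    coordinates are attached later from the structure file."""
    sites = []
    sid = structure_id
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            if structure_id is not None and row["structure_id"] != structure_id:
                continue
            sid = sid or row["structure_id"]
            sites.append(
                LabeledSite(
                    chain=row["chain"],
                    residue_number=int(row["residue"]),
                    coord=(np.nan, np.nan, np.nan),
                    label=row["label"].strip().lower(),
                )
            )
    # coordinates are filled by attach_coordinates; bypass the finite check
    out = object.__new__(LabeledSiteSet)
    out.structure_id = sid or ""
    out.sites = sites
    return out


def attach_coordinates(
    siteset: LabeledSiteSet, ca_coords: dict[tuple[str, int], np.ndarray]
) -> LabeledSiteSet:
    """Resolve each site's Cα coordinate from a {(chain, resnum): xyz} map;
    sites absent from the structure are dropped."""
    resolved = [
        LabeledSite(s.chain, s.residue_number, tuple(ca_coords[(s.chain, s.residue_number)]), s.label)
        for s in siteset.sites
        if (s.chain, s.residue_number) in ca_coords
    ]
    return LabeledSiteSet(siteset.structure_id, resolved)


# ---------------------------------------------------------------------------
# kernel and score
# ---------------------------------------------------------------------------


def _kernel(d: np.ndarray, cfg: Config) -> np.ndarray:
    if cfg.kernel == "reciprocal":
        return 1.0 / (1.0 + d)
    if cfg.kernel == "exponential":
        return np.exp(-d / cfg.kernel_scale)
    raise ValueError(f"unknown kernel {cfg.kernel!r}")


def proximity(query_coord, coords, cfg: Config = DEFAULT_CONFIG) -> float:
    """Mean kernel value between the query Cα and a set of site Cαs."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if coords.shape[0] == 0:
        raise PathProxError("proximity undefined for an empty site set")
    d = np.linalg.norm(coords - np.asarray(query_coord, dtype=float), axis=1)
    return float(np.mean(_kernel(d, cfg)))


def pathprox_score(
    query_coord,
    sites: LabeledSiteSet,
    query_residue: tuple[str, int] | None = None,
    cfg: Config = DEFAULT_CONFIG,
) -> float:
    """Pathogenic-minus-benign proximity; positive ⇒ pathogenic-like
    neighbourhood.  ``query_residue`` (chain, resnum), when given, is
    excluded from both site sets (leave-one-out)."""
    path = sites.coords("pathogenic", exclude=query_residue)
    ben = sites.coords("benign", exclude=query_residue)
    if len(path) == 0 or len(ben) == 0:
        raise PathProxError(
            "two-sided score needs at least one site of each label "
            f"(have {len(path)} pathogenic, {len(ben)} benign)"
        )
    return proximity(query_coord, path, cfg) - proximity(query_coord, ben, cfg)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


@dataclass
class PathProxResult:
    """Score, permutation p-value and provenance for one query on one chain."""

    structure_id: str
    chain: str
    score: float
    p_value: float | None
    n_permutations: int
    n_pathogenic: int
    n_benign: int
    seed: int
    skipped_reason: str | None = None

    def summary(self) -> str:
        p = "n/a" if self.p_value is None else f"{self.p_value:.4g}"
        return (
            f"{self.structure_id} chain {self.chain}: score={self.score:+.4f} "
            f"p={p} ({self.n_pathogenic} pathogenic / {self.n_benign} benign sites, "
            f"{self.n_permutations} permutations)"
        )


def permutation_test(
    query_coord,
    query_residue: tuple[str, int] | None,
    sites: LabeledSiteSet,
    eligible_residues: dict[tuple[str, int], np.ndarray] | list,
    n_perm: int = 199,
    seed: int = 0,
    cfg: Config = DEFAULT_CONFIG,
) -> PathProxResult:
    """Permutation test of the clustering score for one query residue.

    ``eligible_residues`` maps every mapped residue of the chain to its Cα
    coordinate (a list of (address, coord) pairs is also accepted).  Null
    draws place n_pathogenic + n_benign pseudo-sites uniformly without
    replacement on the eligible residues (query excluded) and recompute the
    score.  Reproducible for a fixed seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if isinstance(eligible_residues, dict):
        elig = list(eligible_residues.items())
    else:
        elig = list(eligible_residues)
    elig = [(addr, np.asarray(xyz, float)) for addr, xyz in elig if addr != query_residue]

    path = sites.coords("pathogenic", exclude=query_residue)
    ben = sites.coords("benign", exclude=query_residue)
    n_p, n_b = len(path), len(ben)
    chain = query_residue[0] if query_residue else (sites.sites[0].chain if sites.sites else "?")
    base = dict(
        structure_id=sites.structure_id, chain=chain,
        n_permutations=n_perm, n_pathogenic=n_p, n_benign=n_b, seed=seed,
    )
    if n_p == 0 or n_b == 0:
        # one-sided configuration: report the available proximity, suppress p
        score = np.nan
        try:
            score = proximity(query_coord, path if n_p else ben, cfg) * (1 if n_p else -1)
        except PathProxError:
            pass
        return PathProxResult(score=float(score), p_value=None,
                              skipped_reason="missing label class", **base)
    if len(elig) <= n_p + n_b:
        return PathProxResult(
            score=pathprox_score(query_coord, sites, query_residue, cfg),
            p_value=None,
            skipped_reason=f"too few eligible residues ({len(elig)} <= {n_p + n_b})",
            **base,
        )

    observed = pathprox_score(query_coord, sites, query_residue, cfg)

    # precompute the kernel between the query and every eligible residue;
    # each null score is then a difference of two index-subset means
    coords = np.stack([xyz for _, xyz in elig])
    d = np.linalg.norm(coords - np.asarray(query_coord, float), axis=1)
    k = _kernel(d, cfg)
    rng = np.random.default_rng(seed)
    n_sites = n_p + n_b
    # one uniform-without-replacement draw per permutation via argsort of
    # i.i.d. uniforms (rows are independent random permutations)
    order = np.argsort(rng.random((n_perm, len(elig))), axis=1)[:, :n_sites]
    kp = k[order[:, :n_p]].mean(axis=1)
    kb = k[order[:, n_p:]].mean(axis=1)
    null = kp - kb
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return PathProxResult(score=float(observed), p_value=float(p), **base)


def multimer_test(
    variant_position: int,
    residue_map,
    sites: LabeledSiteSet,
    ca_coords: dict[tuple[str, int], np.ndarray],
    n_perm: int = 199,
    seed: int = 0,
    cfg: Config = DEFAULT_CONFIG,
) -> tuple[PathProxResult | None, list[PathProxResult]]:
    """Evaluate the query on every protomer chain that maps it.

    Labeled sites are replicated across protomer copies by the fixture /
    catalog layer; here each chain is tested with its own eligible-residue
    pool and the minimum-p chain is reported, per-chain detail retained.
    """
    from .structsel import map_residue

    per_chain: list[PathProxResult] = []
    for i, addr in enumerate(map_residue(variant_position, residue_map)):
        key = (addr.chain, addr.residue_number)
        if key not in ca_coords:
            continue
        elig = {k: v for k, v in ca_coords.items() if k[0] == addr.chain}
        res = permutation_test(
            ca_coords[key], key, sites, elig, n_perm=n_perm, seed=seed + i, cfg=cfg
        )
        per_chain.append(res)
    scored = [r for r in per_chain if r.p_value is not None]
    best = min(scored, key=lambda r: r.p_value) if scored else (per_chain[0] if per_chain else None)
    return best, per_chain


def per_residue_scores(
    sites: LabeledSiteSet,
    ca_coords: dict[tuple[str, int], np.ndarray],
    cfg: Config = DEFAULT_CONFIG,
) -> list[dict]:
    """Score track over every mapped residue, for backbone colouring.

    Each residue is treated as a query with leave-one-out exclusion; the
    result is a flat table of rows {chain, residue, score} suitable for CSV
    export and downstream visualisation.
    """
    rows = []
    for (chain, resnum), xyz in sorted(ca_coords.items()):
        try:
            score = pathprox_score(xyz, sites, query_residue=(chain, resnum), cfg=cfg)
        except PathProxError:
            # excluding this residue emptied a label class (it carried the
            # only site of that label); keep the track total by scoring
            # without the exclusion
            score = pathprox_score(xyz, sites, cfg=cfg)
        rows.append({"chain": chain, "residue": resnum, "score": score})
    return rows


def write_score_track(rows: list[dict], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["chain", "residue", "score"])
        w.writeheader()
        for r in rows:
            w.writerow({**r, "score": f"{r['score']:.6f}"})


def ca_coordinates(pdb_path: str | Path) -> dict[tuple[str, int], np.ndarray]:
    """Extract Cα coordinates from a PDB file as {(chain, resnum): xyz}."""
    import gemmi

    st = gemmi.read_structure(str(pdb_path))
    out: dict[tuple[str, int], np.ndarray] = {}
    model = st[0]
    for chain in model:
        for res in chain:
            ca = res.find_atom("CA", "\0")
            if ca is not None:
                out[(chain.name, res.seqid.num)] = np.array(
                    [ca.pos.x, ca.pos.y, ca.pos.z], dtype=float
                )
    return out
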