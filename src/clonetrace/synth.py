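"""Synthetic barcoded-PDX experiments with recorded ground truth.

Emulates the data-generating process of a lentiviral DNA-barcode clonal
tracking study: a high-complexity half-barcode library (the full clone label
space is the Cartesian product of two half-libraries), low-MOI single-integrant
labeling, a severe engraftment bottleneck in the mammary fat pad (MFP),
polyclonal seeding of metastases with a handful of shared dominant clones, and
read-level sequencing noise.  Every simulated quantity (clone labels,
engraftment flags, per-lesion seeder and dominant sets, per-sample barcode-pair
read counts) is recorded in a :class:`GroundTruth` ledger so downstream stages
can be tested for exact recovery.

All randomness flows through :class:`numpy.random.Generator` objects derived
from a single integer seed; identical ``(params, seed)`` give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
SPACER = "TTCG"
READ_LENGTH = 40
HALF_LENGTH = 18

__all__ = [
    "HalfLibrary",
    "GroundTruth",
    "SubclonePhantom",
    "LesionSpec",
    "MouseSpec",
    "SimParams",
    "make_half_library",
    "simulate_experiment",
    "simulate_maf_table",
    "simulate_assignment_trace",
    "write_fasta",
    "write_fastq",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HalfLibrary:
    """A reference set of fixed-length half-barcode sequences.

    Parameters
    ----------
    sequences
        Unique, equal-length nucleotide strings over ACGT.
    min_pairwise_distance
        Guaranteed minimum Hamming distance between any two members.
    ids
        Stable identifiers, parallel to ``sequences``.
    """

    sequences: tuple[str, ...]
    min_pairwise_distance: int
    ids: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("library must contain at least one sequence")
        length = len(self.sequences[0])
        if any(len(s) != length for s in self.sequences):
            raise ValueError("all library sequences must have equal length")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("library sequences must be unique")
        if not self.ids:
            object.__setattr__(
                self, "ids",
                tuple(f"H{i:05d}" for i in range(len(self.sequences))),
            )
        elif len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences must be parallel")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class LesionSpec:
    """One metastatic lesion (or the primary MFP tumor) of a mouse."""

    site: str          # one of MFP, lung, liver, brain
    lesion: str        # label unique within the mouse, e.g. "lung1"
    n_seeders: int = 0  # ignored for the MFP itself


@dataclass(frozen=True)
class MouseSpec:
    name: str
    lesions: tuple[LesionSpec, ...]


@dataclass(frozen=True)
class SimParams:
    """Generating parameters of one simulated barcoding experiment.

    Defaults are chosen to mirror the study conditions at desk scale: MOI 0.2
    single-integrant labeling, ~4 % engraftment (TIC) probability, lesions
    polyclonally seeded by a few hundred clones of which 5 low-abundance
    clones per mouse are amplified by a large dominance factor.
    """

    n_cells: int = 30_000
    moi: float = 0.2
    p_tic: float = 0.04
    mice: tuple[MouseSpec, ...] = ()
    n_dominant: int = 5
    dominance_factor: float = 500.0
    reads_per_sample: int = 100_000
    error_rate: float = 0.0
    junk_fraction: float = 0.05
    nb_mean: float = 100.0
    nb_dispersion: float = 1.0
    seeding_alpha: float = 1.0
    include_reference: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Ledger of everything the generator decided, keyed by mouse/sample.

    ``clone_labels[mouse]`` maps clone index -> tuple of (half1_id, half2_id)
    barcode pairs (one pair per lentiviral integrant).  ``pair_counts`` holds
    the exact number of reads emitted for each barcode pair in each sample,
    which is the quantity a noiseless quantification must recover.
    """

    clone_labels: dict[str, dict[int, tuple[tuple[str, str], ...]]]
    engrafted: dict[str, np.ndarray]
    mfp_abundance: dict[str, np.ndarray]
    seeding_sets: dict[str, set[int]]          # keyed by sample_id
    dominant_sets: dict[str, set[int]]         # keyed by mouse
    lesion_abundance: dict[str, dict[int, float]]  # keyed by sample_id
    pair_counts: dict[str, dict[tuple[str, str], int]]  # keyed by sample_id
    sample_sheet: pd.DataFrame
    params: dict

    def dominant_pairs(self, mouse: str) -> set[tuple[str, str]]:
        labels = self.clone_labels[mouse]
        out: set[tuple[str, str]] = set()
        for clone in self.dominant_sets[mouse]:
            out.update(labels[clone])
        return out


@dataclass(frozen=True)
class SubclonePhantom:
    """Known subclonal structure for generating variant read-count tables.

    ``genotype`` is a binary variant x subclone matrix; ``mixing`` gives
    subclone proportions per sample (columns sum to 1); ``depth`` is the
    sequencing depth per variant per sample.
    """

    genotype: np.ndarray           # (n_variants, n_subclones) in {0,1}
    mixing: np.ndarray             # (n_subclones, n_samples), columns sum to 1
    depth: np.ndarray              # (n_variants, n_samples) positive ints
    variant_ids: tuple[str, ...] = ()
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self):
        g = np.asarray(self.genotype)
        m = np.asarray(self.mixing)
        d = np.asarray(self.depth)
        if not np.isin(g, (0, 1)).all():
            raise ValueError("genotype matrix must be binary")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("mixing proportions must lie in [0, 1]")
        if not np.allclose(m.sum(axis=0), 1.0):
            raise ValueError("mixing proportions must sum to 1 per sample")
        if (d < 1).any():
            raise ValueError("depth must be >= 1 everywhere")
        if g.shape[1] != m.shape[0]:
            raise ValueError("genotype and mixing disagree on subclone count")
        if d.shape != (g.shape[0], m.shape[1]):
            raise ValueError("depth must be variants x samples")
        object.__setattr__(self, "genotype", g)
        object.__setattr__(self, "mixing", m)
        object.__setattr__(self, "depth", d)
        if not self.variant_ids:
            object.__setattr__(
                self, "variant_ids",
                tuple(f"v{i:04d}" for i in range(g.shape[0])))
        if not self.sample_ids:
            object.__setattr__(
                self, "sample_ids",
                tuple(f"s{i:02d}" for i in range(m.shape[1])))


@dataclass(frozen=True)
class AssignmentTrace:
    """Per-iteration variant-to-cluster assignments from an MCMC clustering."""

    labels: np.ndarray            # (n_iterations, n_variants) integer labels
    variant_ids: tuple[str, ...]

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.shape[0] < 1:
            raise ValueError("trace needs >= 1 iteration of labels")
        if lab.shape[1] != len(self.variant_ids):
            raise ValueError("label matrix width must match variant ids")
        object.__setattr__(self, "labels", lab)

    @property
    def n_iterations(self) -> int:
        return self.labels.shape[0]


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

def make_half_library(n: int, length: int = HALF_LENGTH, min_dist: int = 3,
                      seed: int = 0, max_attempts_per_seq: int = 2000,
                      prefix: str = "H") -> HalfLibrary:
    """Draw ``n`` random half-barcodes with pairwise Hamming distance >= ``min_dist``.

    Rejection sampling with a per-sequence attempt cap; raises rather than
    looping forever on infeasible (n, length, min_dist) combinations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_dist > length:
        raise ValueError(
            f"infeasible half-library request: n={n}, length={length}, "
            f"min_dist={min_dist} (min_dist exceeds length)")
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_seq * n
    while len(chosen) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"could not build half-library with n={n}, length={length}, "
                f"min_dist={min_dist} after {attempts} attempts")
        attempts += 1
        cand = rng.integers(0, 4, size=length)
        if min_dist >= 1 and chosen:
            dists = (np.stack(chosen) != cand).sum(axis=1)
            if dists.min() < max(min_dist, 1):
                continue
        elif chosen and any((c == cand).all() for c in chosen):
            continue  # min_dist 0 still requires uniqueness
        chosen.append(cand)
    seqs = tuple("".join("ACGT"[b] for b in row) for row in chosen)
    ids = tuple(f"{prefix}{i:05d}" for i in range(n))
    return HalfLibrary(sequences=seqs, min_pairwise_distance=min_dist, ids=ids)


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float,
             size: int) -> np.ndarray:
    # NB parameterized by mean m and dispersion r (var = m + m^2/r)
    r = dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _reads_for_pairs(pair_counts: dict[tuple[str, str], int],
                     seq_of: dict[str, str], n_junk: int,
                     error_rate: float, rng: np.random.Generator) -> list[str]:
    """Materialize read sequences (half1 + spacer + half2) with noise."""
    templates = []
    for (i1, i2), c in pair_counts.items():
        row = np.frombuffer((seq_of[i1] + SPACER + seq_of[i2]).encode(),
                            dtype=np.uint8)
        templates.extend([row] * c)
    if templates:
        reads = np.stack(templates)
    else:
        reads = np.empty((0, READ_LENGTH), dtype=np.uint8)
    if error_rate > 0 and reads.size:
        mask = rng.random(reads.shape) < error_rate
        # substitute with one of the three *other* bases
        idx = np.searchsorted(ALPHABET, reads[mask])
        shift = rng.integers(1, 4, size=mask.sum())
        reads[mask] = ALPHABET[(idx + shift) % 4]
    if n_junk:
        junk = ALPHABET[rng.integers(0, 4, size=(n_junk, READ_LENGTH))]
        reads = np.vstack([reads, junk]) if reads.size else junk
    out = [row.tobytes().decode() for row in reads]
    # shuffle so junk/errors are not positionally clustered in the FASTQ
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def simulate_experiment(params: SimParams, library: HalfLibrary,
                        seed: int = 0, library2: HalfLibrary | None = None,
                        ) -> tuple[GroundTruth, dict[str, list[str]]]:
    """Simulate a multi-mouse barcoding experiment end to end.

    Per mouse: integrant count per cell ~ Poisson(MOI); unlabeled cells are
    discarded; each integrant draws a barcode pair uniformly from
    library x library; engraftment is Bernoulli(p_TIC) per labeled clone; MFP
    abundance of engrafted clones follows a negative-binomial clone-size
    model; each lesion samples seeders without replacement with probability
    proportional to MFP abundance ** seeding_alpha; the mouse's dominant set
    (shared by all its lesions, drawn from low-abundance MFP clones) is
    amplified by the dominance factor inside lesions.  Reads are multinomial
    over clone abundance with iid substitution errors and a junk-read
    fraction of uniform random 40-mers.

    Returns the ground-truth ledger and a dict of per-sample read sequences.
    """
    if params.dominance_factor <= 1:
        raise ValueError("dominance_factor must exceed 1 to create dominance")
    if not params.mice:
        raise ValueError("params.mice must define at least one mouse")
    lib2 = library2 if library2 is not None else library
    ss = np.random.SeedSequence(seed)
    mouse_seeds = ss.spawn(len(params.mice))

    clone_labels: dict[str, dict[int, tuple[tuple[str, str], ...]]] = {}
    engrafted: dict[str, np.ndarray] = {}
    mfp_abundance: dict[str, np.ndarray] = {}
    seeding_sets: dict[str, set[int]] = {}
    dominant_sets: dict[str, set[int]] = {}
    lesion_abundance: dict[str, dict[int, float]] = {}
    pair_counts: dict[str, dict[tuple[str, str], int]] = {}
    reads: dict[str, list[str]] = {}
    sheet_rows: list[dict] = []

    seq1 = dict(zip(library.ids, library.sequences))
    seq2 = dict(zip(lib2.ids, lib2.sequences))
    seq_of = {**seq1, **seq2}

    for mouse, mseed in zip(params.mice, mouse_seeds):
        rng = np.random.default_rng(mseed)
        integrants = rng.poisson(params.moi, size=params.n_cells)
        k = integrants[integrants > 0]
        n_clones = len(k)
        labels: dict[int, tuple[tuple[str, str], ...]] = {}
        for c in range(n_clones):
            i1 = rng.integers(0, len(library), size=k[c])
            i2 = rng.integers(0, len(lib2), size=k[c])
            labels[c] = tuple((library.ids[a], lib2.ids[b])
                              for a, b in zip(i1, i2))
        eng = rng.random(n_clones) < params.p_tic
        abund = np.zeros(n_clones)
        abund[eng] = _nb_draw(rng, params.nb_mean, params.nb_dispersion,
                              int(eng.sum()))
        clone_labels[mouse.name] = labels
        engrafted[mouse.name] = eng
        mfp_abundance[mouse.name] = abund

        detectable = np.flatnonzero(abund > 0)
        if detectable.size == 0:
            raise ValueError(
                f"mouse {mouse.name}: no engrafted clone has positive "
                "abundance; increase n_cells or p_tic")
        # dominant clones come from the low-abundance half of the MFP
        med = np.median(abund[detectable])
        low = detectable[abund[detectable] <= med]
        pool = low if low.size >= params.n_dominant else detectable
        if pool.size < params.n_dominant:
            raise ValueError(
                f"mouse {mouse.name}: n_dominant={params.n_dominant} exceeds "
                f"{pool.size} candidate clones")
        dom = set(rng.choice(pool, size=params.n_dominant, replace=False)
                  .tolist())
        dominant_sets[mouse.name] = dom

        for les in mouse.lesions:
            sample_id = f"{mouse.name}_{les.lesion}"
            sheet_rows.append({"sample_id": sample_id, "mouse": mouse.name,
                               "site": les.site, "lesion": les.lesion})
            if les.site == "MFP":
                clone_ab = {int(c): float(abund[c]) for c in detectable}
            else:
                if les.n_seeders > detectable.size:
                    raise ValueError(
                        f"lesion {sample_id}: n_seeders={les.n_seeders} "
                        f"exceeds {detectable.size} engrafted clones")
                others = np.array(sorted(set(detectable.tolist()) - dom))
                n_extra = max(les.n_seeders - len(dom), 0)
                w = abund[others] ** params.seeding_alpha
                extra = rng.choice(others, size=min(n_extra, others.size),
                                   replace=False, p=w / w.sum())
                seeders = dom | set(int(x) for x in extra)
                seeding_sets[sample_id] = seeders
                clone_ab = {
                    c: float(abund[c]) * (params.dominance_factor
                                          if c in dom else 1.0)
                    for c in seeders}
            lesion_abundance[sample_id] = clone_ab
            pc, rd = _emit_sample(clone_ab, labels, seq_of,
                                  params.reads_per_sample,
                                  params.junk_fraction, params.error_rate,
                                  rng)
            pair_counts[sample_id] = pc
            reads[sample_id] = rd

        if params.include_reference:
            sample_id = f"{mouse.name}_reference"
            sheet_rows.append({"sample_id": sample_id, "mouse": mouse.name,
                               "site": "reference", "lesion": "reference"})
            ref_ab = _nb_draw(rng, params.nb_mean, params.nb_dispersion,
                              n_clones).astype(float)
            ref_ab[ref_ab == 0] = 1.0  # every labeled clone is in the pellet
            clone_ab = {c: ref_ab[c] for c in range(n_clones)}
            lesion_abundance[sample_id] = clone_ab
            pc, rd = _emit_sample(clone_ab, labels, seq_of,
                                  params.reads_per_sample,
                                  params.junk_fraction, params.error_rate,
                                  rng)
            pair_counts[sample_id] = pc
            reads[sample_id] = rd

    sheet = pd.DataFrame(sheet_rows)
    gt = GroundTruth(clone_labels=clone_labels, engrafted=engrafted,
                     mfp_abundance=mfp_abundance, seeding_sets=seeding_sets,
                     dominant_sets=dominant_sets,
                     lesion_abundance=lesion_abundance,
                     pair_counts=pair_counts, sample_sheet=sheet,
                     params={**params.to_dict(), "seed": seed})
    return gt, reads


def _emit_sample(clone_ab: dict[int, float],
                 labels: dict[int, tuple[tuple[str, str], ...]],
                 seq_of: dict[str, str], n_reads: int, junk_fraction: float,
                 error_rate: float, rng: np.random.Generator,
                 ) -> tuple[dict[tuple[str, str], int], list[str]]:
    clones = sorted(clone_ab)
    w = np.array([clone_ab[c] for c in clones], dtype=float)
    n_junk = int(round(junk_fraction * n_reads))
    n_real = n_reads - n_junk
    counts = rng.multinomial(n_real, w / w.sum())
    pair_counts: dict[tuple[str, str], int] = {}
    for c, cnt in zip(clones, counts):
        if cnt == 0:
            continue
        pairs = labels[c]
        if len(pairs) == 1:
            split = [cnt]
        else:  # multi-integrant clone: reads spread evenly over its pairs
            split = rng.multinomial(cnt, np.full(len(pairs), 1 / len(pairs)))
        for p, s in zip(pairs, split):
            if s:
                pair_counts[p] = pair_counts.get(p, 0) + int(s)
    rd = _reads_for_pairs(pair_counts, seq_of, n_junk, error_rate, rng)
    return pair_counts, rd


# ---------------------------------------------------------------------------
# Variant-table and trace simulation
# ---------------------------------------------------------------------------

def simulate_maf_table(phantom: SubclonePhantom, seed: int = 0,
                       platform: str = "WES", n_callers: int = 3,
                       ) -> pd.DataFrame:
    """Binomial read sampling of subclonal mutant-allele frequencies.

    Expected MAF of variant v in sample s is
    ``0.5 * sum_k genotype[v, k] * mixing[k, s]`` (heterozygous-diploid
    convention); alternate reads ~ Binomial(depth, MAF).  Returns a long-form
    variant table with one row per (variant, sample).
    """
    rng = np.random.default_rng(seed)
    mu = 0.5 * phantom.genotype @ phantom.mixing
    if (mu > 1).any():
        raise ValueError("expected MAF exceeds 1; phantom invariants violated")
    alt = rng.binomial(phantom.depth, mu)
    ref = phantom.depth - alt
    v_idx, s_idx = np.meshgrid(np.arange(mu.shape[0]),
                               np.arange(mu.shape[1]), indexing="ij")
    return pd.DataFrame({
        "variant_id": np.array(phantom.variant_ids)[v_idx.ravel()],
        "sample_id": np.array(phantom.sample_ids)[s_idx.ravel()],
        "ref_reads": ref.ravel(),
        "alt_reads": alt.ravel(),
        "n_callers": n_callers,
        "germline_vaf": 0.0,
        "in_population_db": False,
        "is_silent": False,
        "region_class": "exonic",
        "platform": platform,
    })


def simulate_assignment_trace(true_clusters: dict[str, int], n_iters: int,
                              flip_rate: float | dict[str, float],
                              seed: int = 0) -> AssignmentTrace:
    """Noisy MCMC-style trace around a known variant clustering.

    Each iteration copies the true assignment, then independently reassigns
    each variant to a uniformly chosen *other* cluster with probability
    ``flip_rate``.  ``flip_rate`` may be a single probability or a per-variant
    mapping (e.g. to plant stable clusters next to unstable ones).
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    variants = tuple(true_clusters)
    if isinstance(flip_rate, dict):
        rates = np.array([flip_rate[v] for v in variants])
    else:
        rates = np.full(len(variants), flip_rate)
    if ((rates < 0) | (rates >= 1)).any():
        raise ValueError("flip_rate must lie in [0, 1)")
    clusters = sorted(set(true_clusters.values()))
    if len(clusters) < 2 and (rates > 0).any():
        raise ValueError("cannot flip assignments with a single cluster")
    code = {c: i for i, c in enumerate(clusters)}
    base = np.array([code[true_clusters[v]] for v in variants])
    rng = np.random.default_rng(seed)
    labels = np.tile(base, (n_iters, 1))
    if (rates > 0).any():
        flips = rng.random(labels.shape) < rates[None, :]
        offset = rng.integers(1, len(clusters), size=int(flips.sum()))
        labels[flips] = (labels[flips] + offset) % len(clusters)
    inv = np.array(clusters)
    return AssignmentTrace(labels=inv[labels], variant_ids=variants)


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def write_fasta(library: HalfLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for bid, seq in zip(library.ids, library.sequences):
            fh.write(f">{bid}\n{seq}\n")


def write_fastq(reads: list[str], path: str | Path,
                quality_char: str = "I") -> None:
    """Write reads with a constant quality string (quality is ignored downstream)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_ground_truth(gt: GroundTruth, outdir: str | Path) -> None:
    """Persist the ground-truth ledger as TSV tables plus a JSON params sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gt.sample_sheet.to_csv(outdir / "sample_sheet.csv", index=False)
    with open(outdir / "params.json", "w") as fh:
        json.dump(gt.params, fh, indent=2, default=str)
    rows = []
    for sample, pc in gt.pair_counts.items():
        for (h1, h2), c in sorted(pc.items()):
            rows.append({"sample_id": sample, "barcode": f"{h1}:{h2}",
                         "true_count": c})
    pd.DataFrame(rows).to_csv(outdir / "true_pair_counts.tsv", sep="\t",
                              index=False)
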