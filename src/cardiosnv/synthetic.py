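"""Synthetic single-cell WGS cohort generator.

Emulates, at the evidence-table level (downstream of alignment), the data a
single-cell somatic-SNV study produces from MDA-amplified nuclei:

* a small reference genome (stand-in for the autosomes),
* phased germline heterozygous SNVs per donor,
* per-cell somatic truth accumulating linearly with donor age, with
  trinucleotide contexts drawn from a configurable signature mixture,
* MDA amplification evidence: locus/allelic dropout, negative-binomial read
  depth modulated by per-bin log-normal amplification unevenness,
  linked-read counts against the nearest phased germline het, and C>T-rich
  single-strand amplification artifacts,
* tetraploid nuclei as in-silico mixtures of two independent diploid
  amplification realizations sharing the donor's germline.

Every generator is deterministic given its seed. Coordinates are 0-based
half-open internally; emitted VCF is 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import contexts
from .contexts import CONTEXT_96, CONTEXT_INDEX

#: Age-linear somatic accumulation rates (sSNV per Mb of DNA per year) by
#: cell type, as configured study conditions.
RATE_PER_MB_PER_YEAR = {
    "cardiomyocyte": 0.010,
    "neuron": 0.003,
    "hepatocyte": 0.009,
    "lymphocyte": 0.004,
}

#: Default donor panel: twelve donors spanning infancy to old age
#: (three infants <4 y, six middle-aged 30-66 y, three aged >75 y).
DEFAULT_DONOR_AGES = (0.4, 2.0, 4.0, 30.0, 35.0, 39.0, 49.2, 63.0, 66.0, 75.0, 75.3, 82.2)

EVIDENCE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "depth", "ref_reads", "alt_reads",
    "het_pos", "c_ref_h1", "c_ref_h2", "c_alt_h1", "c_alt_h2",
]


class ReferenceGenome:
    """In-memory reference: ordered chromosomes of ACGT sequence.

    Caches a per-chromosome triplet code index so positions matching a given
    trinucleotide context can be sampled in O(1) after one pass.
    """

    def __init__(self, chrom_names: list[str], sequences: list[str]):
        if len(chrom_names) != len(sequences):
            raise ValueError("chrom_names and sequences length mismatch")
        self.chrom_names = list(chrom_names)
        self.sequences = dict(zip(chrom_names, sequences))
        self._trip_index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._gc_cache: dict[int, dict[str, tuple]] = {}

    def __len__(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    @property
    def haploid_mb(self) -> float:
        return len(self) / 1e6

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def _index(self, chrom: str):
        # sorted-by-code position index: positions_for_code(c) is a slice
        if chrom not in self._trip_index:
            trip = contexts.encode_triplets(self.sequences[chrom])
            order = np.argsort(trip, kind="stable").astype(np.int64)
            sorted_codes = trip[order]
            starts = np.searchsorted(sorted_codes, np.arange(65))
            self._trip_index[chrom] = (order, starts[:-1], starts[1:])
        return self._trip_index[chrom]

    def bin_gc(self, bin_size: int) -> dict[str, tuple]:
        """Per-chromosome (starts, ends, gc) for fixed windows; cached."""
        if bin_size not in self._gc_cache:
            out = {}
            for chrom in self.chrom_names:
                L = self.chrom_length(chrom)
                starts = np.arange(0, L, bin_size)
                ends = np.minimum(starts + bin_size, L)
                seq = self.sequences[chrom]
                gc = np.array(
                    [
                        (seq.count("G", s, e) + seq.count("C", s, e)) / max(e - s, 1)
                        for s, e in zip(starts, ends)
                    ]
                )
                out[chrom] = (starts, ends, gc)
            self._gc_cache[bin_size] = out
        return self._gc_cache[bin_size]

    def context_positions(self, chrom: str, code: int) -> np.ndarray:
        """All internal positions on ``chrom`` whose forward triplet has ``code``."""
        order, lo, hi = self._index(chrom)
        return order[lo[code]:hi[code]]

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.chrom_names:
                fh.write(f">{name}\n")
                seq = self.sequences[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        names = list(fa.keys())
        return cls(names, [str(fa[n][:]).upper() for n in names])


@dataclass
class AmplificationParams:
    """MDA amplification model parameters for one diploid realization.

    locus_dropout_rate
        Probability that a site fails to amplify on both chromatids at once
        (regional amplification failure, modelled per site).
    allelic_dropout_rate
        Per-chromatid probability of losing one allele at an amplified site.
    mean_depth
        Target mean total read depth of the cell.
    depth_dispersion
        Negative-binomial size parameter r (variance = m + m^2/r).
    unevenness_sigma
        Log-scale s.d. of the per-bin multiplicative amplification factor.
    artifact_rate_per_mb
        MDA polymerase C>T-rich artifact sites per Mb per realization.
    artifact_profile
        96-vector of artifact context probabilities (defaults to the shipped
        scF-like fixture).
    linkage_window
        Maximum candidate-to-het distance (bp) for read-pair linkage.
    """

    locus_dropout_rate: float = 0.10
    allelic_dropout_rate: float = 0.10
    mean_depth: float = 30.0
    depth_dispersion: float = 10.0
    unevenness_sigma: float = 0.30
    artifact_rate_per_mb: float = 2.0
    artifact_profile: np.ndarray | None = None
    artifact_geom_p: float = 0.5
    linkage_window: int = 500
    bin_size: int = 100_000

    def __post_init__(self):
        for name in ("locus_dropout_rate", "allelic_dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.artifact_profile is not None:
            p = np.asarray(self.artifact_profile, dtype=float)
            if p.shape != (96,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError("artifact_profile must be a 96-simplex vector")
            self.artifact_profile = p

    def resolved_artifact_profile(self) -> np.ndarray:
        if self.artifact_profile is None:
            from .signatures import load_reference_signatures

            return load_reference_signatures()["scF_like"].to_numpy()
        return self.artifact_profile


@dataclass
class CohortSpec:
    """Study design of a synthetic cohort (one cell type, one ploidy arm)."""

    donors: list[tuple[str, float]] = field(
        default_factory=lambda: [
            (f"donor{i + 1:02d}", a) for i, a in enumerate(DEFAULT_DONOR_AGES)
        ]
    )
    cells_per_donor: int = 4
    cell_type: str = "cardiomyocyte"
    ploidy: int = 4
    rate_per_mb_per_year: float | None = None
    intercept_per_mb: float = 0.05
    signature_mix: dict[str, float] | None = None
    het_density_per_kb: float = 0.67
    amp_params: AmplificationParams = field(default_factory=AmplificationParams)
    seed: int = 0

    def __post_init__(self):
        if self.ploidy not in (2, 4):
            raise ValueError("ploidy must be 2 or 4")
        if self.rate_per_mb_per_year is None:
            self.rate_per_mb_per_year = RATE_PER_MB_PER_YEAR[self.cell_type]
        if self.rate_per_mb_per_year < 0 or self.intercept_per_mb < 0:
            raise ValueError("rate and intercept must be non-negative")
        if self.signature_mix is None:
            self.signature_mix = {"SBS5_like": 0.7, "SBS18_like": 0.3}
        w = np.array(list(self.signature_mix.values()), dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("signature_mix weights must be non-negative and sum to 1")


@dataclass
class CellData:
    """One simulated nucleus: observable evidence plus hidden truth."""

    cell_id: str
    donor_id: str
    age: float
    cell_type: str
    ploidy: int
    evidence: pd.DataFrame
    bins: pd.DataFrame
    truth_somatic: pd.DataFrame
    truth_artifacts: pd.DataFrame


@dataclass
class Cohort:
    reference: ReferenceGenome
    germline: dict[str, pd.DataFrame]  # donor_id -> phased hets
    cells: list[CellData]
    spec: CohortSpec

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_id": c.cell_id,
                    "donor_id": c.donor_id,
                    "age": c.age,
                    "cell_type": c.cell_type,
                    "ploidy": c.ploidy,
                }
                for c in self.cells
            ]
        )


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_reference(
    n_chrom: int = 2,
    chrom_length: int = 10_000_000,
    gc_fraction: float = 0.41,
    seed: int | np.random.SeedSequence = 0,
) -> ReferenceGenome:
    """I.i.d. random genome with the requested GC content.

    P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2 at every position.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10 kb")
    if not 0.0 <= gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in [0, 1)")
    rng = _rng(seed)
    probs = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    names, seqs = [], []
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in range(n_chrom):
        draw = rng.choice(4, size=int(chrom_length), p=probs)
        seqs.append(base_bytes[draw].tobytes().decode())
        names.append(f"chr{i + 1}")
    return ReferenceGenome(names, seqs)


def generate_germline(
    ref: ReferenceGenome,
    het_density_per_kb: float = 0.67,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Phased germline heterozygous SNVs as a Poisson process along the genome.

    Returns columns chrom, pos (0-based), ref, alt, hap (0 = allele on
    haplotype 1, i.e. VCF GT 1|0; 1 = GT 0|1).
    """
    if het_density_per_kb <= 0:
        raise ValueError("het_density_per_kb must be > 0")
    if het_density_per_kb > 1000:
        raise ValueError("het density exceeds one per bp")
    rng = _rng(seed)
    rows = []
    for chrom in ref.chrom_names:
        L = ref.chrom_length(chrom)
        n = rng.poisson(het_density_per_kb * L / 1000.0)
        n = min(n, L - 2)
        pos = np.sort(rng.choice(L - 2, size=n, replace=False) + 1)
        seq = ref.sequences[chrom]
        refs = np.array([seq[p] for p in pos])
        alts = np.empty(n, dtype="<U1")
        for b in "ACGT":
            mask = refs == b
            others = [x for x in "ACGT" if x != b]
            alts[mask] = np.array(others)[rng.integers(0, 3, int(mask.sum()))]
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "ref": refs,
                    "alt": alts,
                    "hap": rng.integers(0, 2, n).astype(np.int8),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _sample_context_positions(
    ref: ReferenceGenome,
    class_indices: np.ndarray,
    rng: np.random.Generator,
    forbidden: set[tuple[str, int]],
    max_retries: int = 50,
) -> pd.DataFrame:
    """Pick a genome position with matching trinucleotide context per class.

    A class is matched by forward-strand occurrences of its pyrimidine
    triplet (variant = pyr>alt) or of the reverse complement (variant is the
    complemented substitution on the purine base).
    """
    chrom_weights = np.array([ref.chrom_length(c) for c in ref.chrom_names], dtype=float)
    chrom_weights /= chrom_weights.sum()
    out_chrom, out_pos, out_ref, out_alt = [], [], [], []
    for ci in class_indices:
        label = CONTEXT_96[ci]
        five, rb, ab, three = contexts.parse_class(label)
        trip = five + rb + three
        fwd_code = contexts.triplet_code(trip)
        rev_code = contexts.triplet_code(contexts.revcomp(trip))
        placed = False
        for _ in range(max_retries):
            chrom = ref.chrom_names[rng.choice(len(ref.chrom_names), p=chrom_weights)]
            fwd = ref.context_positions(chrom, fwd_code)
            rev = ref.context_positions(chrom, rev_code)
            total = len(fwd) + len(rev)
            if total == 0:
                continue
            j = rng.integers(0, total)
            if j < len(fwd):
                p, vref, valt = int(fwd[j]), rb, ab
            else:
                p = int(rev[j - len(fwd)])
                vref, valt = contexts.COMPLEMENT[rb], contexts.COMPLEMENT[ab]
            if (chrom, p) in forbidden:
                continue
            forbidden.add((chrom, p))
            out_chrom.append(chrom)
            out_pos.append(p)
            out_ref.append(vref)
            out_alt.append(valt)
            placed = True
            break
        if not placed:
            raise RuntimeError(f"no available position with context {label}")
    return pd.DataFrame(
        {
            "chrom": out_chrom,
            "pos": np.array(out_pos, dtype=np.int64),
            "ref": out_ref,
            "alt": out_alt,
            "context": [CONTEXT_96[i] for i in class_indices],
        }
    )


def generate_somatic(
    ref: ReferenceGenome,
    age: float,
    rate_per_mb_per_year: float,
    intercept_per_mb: float,
    ploidy: int,
    signature_mix: dict[str, float],
    seed: int | np.random.SeedSequence = 0,
    germline: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Somatic truth for one cell.

    The somatic count is Poisson with mean (intercept + rate x age) x
    cell_genome_Mb where cell_genome_Mb = ploidy x haploid Mb. Contexts are
    drawn from the signature mixture; each variant lands on one haplotype of
    one origin copy (origin is meaningful for tetraploid cells only).
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    from .signatures import load_reference_signatures

    rng = _rng(seed)
    genome_mb = ploidy * ref.haploid_mb
    mean = (intercept_per_mb + rate_per_mb_per_year * age) * genome_mb
    n = rng.poisson(mean)
    sigs = load_reference_signatures()
    profile = np.zeros(96)
    for name, w in signature_mix.items():
        profile += w * sigs[name].to_numpy()
    profile /= profile.sum()
    class_idx = rng.choice(96, size=n, p=profile)
    forbidden = set()
    if germline is not None:
        forbidden = set(zip(germline["chrom"], germline["pos"].astype(int)))
    df = _sample_context_positions(ref, class_idx, rng, forbidden)
    df["hap"] = rng.integers(0, 2, n).astype(np.int8)
    n_origins = ploidy // 2
    df["origin"] = rng.integers(0, n_origins, n).astype(np.int8)
    return df


def generate_artifacts(
    ref: ReferenceGenome,
    params: AmplificationParams,
    n_realizations: int,
    rng: np.random.Generator,
    forbidden: set[tuple[str, int]],
) -> pd.DataFrame:
    """MDA artifact truth sites, each owned by one chromatid of one realization."""
    profile = params.resolved_artifact_profile()
    frames = []
    for r in range(n_realizations):
        n = rng.poisson(params.artifact_rate_per_mb * ref.haploid_mb)
        class_idx = rng.choice(96, size=n, p=profile)
        df = _sample_context_positions(ref, class_idx, rng, forbidden)
        df["hap"] = rng.integers(0, 2, n).astype(np.int8)
        df["origin"] = np.int8(r)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "context", "hap", "origin"]
        )
    return pd.concat(frames, ignore_index=True)


def _global_bins(ref: ReferenceGenome, bin_size: int) -> tuple[dict[str, int], int]:
    offsets, total = {}, 0
    for chrom in ref.chrom_names:
        offsets[chrom] = total
        total += -(-ref.chrom_length(chrom) // bin_size)
    return offsets, total


def _assemble_sites(
    germline: pd.DataFrame,
    somatic: pd.DataFrame,
    artifacts: pd.DataFrame,
) -> pd.DataFrame:
    """Unified per-cell site table with per-site role annotations."""
    g = germline[["chrom", "pos", "ref", "alt", "hap"]].copy()
    g["kind"] = "germline"
    g["origin"] = np.int8(-1)
    s = somatic[["chrom", "pos", "ref", "alt", "hap", "origin"]].copy()
    s["kind"] = "somatic"
    a = artifacts[["chrom", "pos", "ref", "alt", "hap", "origin"]].copy()
    a["kind"] = "artifact"
    sites = pd.concat([g, s, a], ignore_index=True)
    sites["pos"] = sites["pos"].astype(np.int64)
    sites["hap"] = sites["hap"].astype(np.int8)
    sites["origin"] = sites["origin"].astype(np.int8)
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if sites.duplicated(["chrom", "pos"]).any():
        raise ValueError("position collision between germline/somatic/artifact sites")
    return sites


def _nearest_het(sites: pd.DataFrame, germline: pd.DataFrame, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Nearest other germline het per site (position, distance; -1 if none).

    Equidistant neighbours break toward the lower coordinate. Germline sites
    never link to themselves (they link to the next-nearest het), which is
    what sensitivity estimation from pseudo-somatic hets requires.
    """
    het_pos = np.full(len(sites), -1, dtype=np.int64)
    het_dist = np.full(len(sites), np.iinfo(np.int64).max, dtype=np.int64)
    for chrom, idx in sites.groupby("chrom", sort=False).groups.items():
        H = np.sort(germline.loc[germline["chrom"] == chrom, "pos"].to_numpy())
        if len(H) == 0:
            continue
        P = sites.loc[idx, "pos"].to_numpy()
        is_self = sites.loc[idx, "kind"].to_numpy() == "germline"
        j = np.searchsorted(H, P)
        cand = np.stack(
            [
                H[np.clip(j - 2, 0, len(H) - 1)],
                H[np.clip(j - 1, 0, len(H) - 1)],
                H[np.clip(j, 0, len(H) - 1)],
                H[np.clip(j + 1, 0, len(H) - 1)],
            ]
        )  # 4 x n candidate neighbours
        dist = np.abs(cand - P[None, :])
        # exclude the site itself when it is a germline het
        dist[(cand == P[None, :]) & is_self[None, :]] = np.iinfo(np.int64).max
        # tie -> lower coordinate: among equal distances prefer smaller pos
        order = np.lexsort((cand, dist), axis=0)
        best = order[0]
        cols = np.arange(len(P))
        bp, bd = cand[best, cols], dist[best, cols]
        ok = bd <= window
        hp = np.where(ok, bp, -1)
        hd = np.where(ok, bd, np.iinfo(np.int64).max)
        het_pos[np.asarray(idx)] = hp
        het_dist[np.asarray(idx)] = hd
    return het_pos, het_dist


def simulate_realization(
    sites: pd.DataFrame,
    germline: pd.DataFrame,
    ref: ReferenceGenome,
    params: AmplificationParams,
    origin: int,
    per_copy_mean: float,
    seed: int | np.random.SeedSequence,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one diploid MDA amplification realization.

    Returns (evidence, bins). ``origin`` marks which somatic/artifact sites
    this realization carries on its chromatids; all other sites contribute
    reference reads only.
    """
    rng = _rng(seed)
    n = len(sites)
    hap = sites["hap"].to_numpy()
    kind = sites["kind"].to_numpy()
    owner = sites["origin"].to_numpy()

    # copy c (= haplotype c chromatid) carries the alt allele fully for
    # germline hets and owned somatic variants; artifacts are sub-clonal on
    # their chromatid (ref molecules remain).
    carries_alt = np.zeros((n, 2), dtype=bool)
    for c in (0, 1):
        carries_alt[:, c] = (hap == c) & (
            (kind == "germline") | ((kind == "somatic") & (owner == origin))
        )
    artifact_here = (kind == "artifact") & (owner == origin)

    locus = rng.random(n) < params.locus_dropout_rate
    adrop = rng.random((n, 2)) < params.allelic_dropout_rate
    alive = (~locus[:, None]) & (~adrop)

    offsets, n_bins = _global_bins(ref, params.bin_size)
    chrom_off = sites["chrom"].map(offsets).to_numpy()
    bin_idx = chrom_off + sites["pos"].to_numpy() // params.bin_size
    sigma = params.unevenness_sigma
    factors = np.exp(rng.normal(-sigma**2 / 2.0, sigma, n_bins)) if sigma > 0 else np.ones(n_bins)

    mean = per_copy_mean * factors[bin_idx][:, None] * alive
    r = params.depth_dispersion
    reads = np.zeros((n, 2), dtype=np.int64)
    pos_mask = mean > 0
    reads[pos_mask] = rng.negative_binomial(r, r / (r + mean[pos_mask]))

    alt_on_copy = np.where(carries_alt, reads, 0)
    # artifact alt support: geometric(p), capped by the chromatid's reads
    if artifact_here.any():
        idx = np.where(artifact_here)[0]
        ac = hap[idx]
        support = rng.geometric(params.artifact_geom_p, len(idx))
        alt_on_copy[idx, ac] = np.minimum(support, reads[idx, ac])
    ref_on_copy = reads - alt_on_copy

    het_pos, het_dist = _nearest_het(sites, germline, params.linkage_window)
    linked = het_pos >= 0
    p_link = np.where(linked, 1.0 - het_dist / float(params.linkage_window), 0.0)
    p_link = np.clip(p_link, 0.0, 1.0)

    c_ref = np.zeros((n, 2), dtype=np.int64)
    c_alt = np.zeros((n, 2), dtype=np.int64)
    for c in (0, 1):
        c_ref[:, c] = rng.binomial(ref_on_copy[:, c], p_link)
        c_alt[:, c] = rng.binomial(alt_on_copy[:, c], p_link)

    evidence = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "ref": sites["ref"].to_numpy(),
            "alt": sites["alt"].to_numpy(),
            "depth": reads.sum(axis=1),
            "ref_reads": ref_on_copy.sum(axis=1),
            "alt_reads": alt_on_copy.sum(axis=1),
            "het_pos": het_pos,
            "c_ref_h1": c_ref[:, 0],
            "c_ref_h2": c_ref[:, 1],
            "c_alt_h1": c_alt[:, 0],
            "c_alt_h2": c_alt[:, 1],
            # hidden per-copy read counts (dropped before tables are written;
            # used to annotate truth with interfering-copy status)
            "_r_h1": reads[:, 0],
            "_r_h2": reads[:, 1],
        }
    )

    # binned coverage for evenness QC: expected reads per bin under the same
    # unevenness factor, with NB counting noise
    bin_rows = []
    gc_bins = ref.bin_gc(params.bin_size)
    for chrom in ref.chrom_names:
        starts, ends, gc = gc_bins[chrom]
        bidx = offsets[chrom] + starts // params.bin_size
        base = per_copy_mean * 2.0 * (ends - starts) / 150.0  # read-equivalents
        m = base * factors[bidx]
        counts = rng.negative_binomial(r, r / (r + m))
        bin_rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, "gc": gc, "reads": counts}
            )
        )
    bins = pd.concat(bin_rows, ignore_index=True)
    return evidence, bins


def make_tetraploid(ev_a: pd.DataFrame, ev_b: pd.DataFrame) -> pd.DataFrame:
    """In-silico mixture of two diploid realizations: sum read counts sitewise.

    Both realizations must cover the identical site set (same germline and
    the same union of somatic/artifact positions).
    """
    key = ["chrom", "pos", "ref", "alt"]
    if len(ev_a) != len(ev_b) or not (
        ev_a[key].reset_index(drop=True).equals(ev_b[key].reset_index(drop=True))
    ):
        raise ValueError("realizations do not share the same site table")
    out = ev_a.copy()
    for col in ["depth", "ref_reads", "alt_reads", "c_ref_h1", "c_ref_h2", "c_alt_h1", "c_alt_h2"]:
        out[col] = ev_a[col].to_numpy() + ev_b[col].to_numpy()
    return out


def merge_bins(bins_a: pd.DataFrame, bins_b: pd.DataFrame) -> pd.DataFrame:
    out = bins_a.copy()
    out["reads"] = bins_a["reads"].to_numpy() + bins_b["reads"].to_numpy()
    return out


def simulate_cell(
    ref: ReferenceGenome,
    germline: pd.DataFrame,
    params: AmplificationParams,
    ploidy: int,
    age: float,
    rate_per_mb_per_year: float,
    intercept_per_mb: float,
    signature_mix: dict[str, float],
    seed: int | np.random.SeedSequence,
    cell_id: str = "cell",
    donor_id: str = "donor",
    cell_type: str = "cardiomyocyte",
) -> CellData:
    """Simulate one nucleus end to end (truth + amplification evidence).

    Tetraploid nuclei are simulated as two independent diploid realizations
    sharing the germline, each at half the per-copy depth, merged site-wise.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_som, s_art, s_a, s_b = ss.spawn(4)
    somatic = generate_somatic(
        ref, age, rate_per_mb_per_year, intercept_per_mb, ploidy,
        signature_mix, seed=s_som, germline=germline,
    )
    n_real = ploidy // 2
    forbidden = set(zip(germline["chrom"], germline["pos"].astype(int)))
    forbidden |= set(zip(somatic["chrom"], somatic["pos"].astype(int)))
    artifacts = generate_artifacts(ref, params, n_real, _rng(s_art), forbidden)
    sites = _assemble_sites(germline, somatic, artifacts)
    per_copy = params.mean_depth / 2.0 / n_real
    ev_a, bins_a = simulate_realization(sites, germline, ref, params, 0, per_copy, s_a)
    if n_real == 1:
        evidence, bins = ev_a.drop(columns=["_r_h1", "_r_h2"]), bins_a
    else:
        ev_b, bins_b = simulate_realization(sites, germline, ref, params, 1, per_copy, s_b)
        # annotate somatic truth with the interfering same-haplotype copy's
        # read count from the other realization (drives 4n callability)
        if len(somatic):
            pos_index = pd.MultiIndex.from_frame(ev_a[["chrom", "pos"]])
            loc = pos_index.get_indexer(pd.MultiIndex.from_frame(somatic[["chrom", "pos"]]))
            hap_col = somatic["hap"].map({0: "_r_h1", 1: "_r_h2"})
            other = np.where(somatic["origin"].to_numpy() == 0, 1, 0)
            vals = np.empty(len(somatic), dtype=np.int64)
            for i, (j, col, o) in enumerate(zip(loc, hap_col, other)):
                vals[i] = (ev_b if o == 1 else ev_a)[col].iloc[j]
            somatic = somatic.assign(interferer_reads=vals)
        evidence = make_tetraploid(
            ev_a.drop(columns=["_r_h1", "_r_h2"]),
            ev_b.drop(columns=["_r_h1", "_r_h2"]),
        )
        bins = merge_bins(bins_a, bins_b)
    return CellData(
        cell_id=cell_id,
        donor_id=donor_id,
        age=age,
        cell_type=cell_type,
        ploidy=ploidy,
        evidence=evidence,
        bins=bins,
        truth_somatic=somatic,
        truth_artifacts=artifacts,
    )


def simulate_cohort(spec: CohortSpec, ref: ReferenceGenome | None = None) -> Cohort:
    """Simulate the full cohort defined by ``spec`` (deterministic in spec.seed)."""
    root = np.random.SeedSequence(spec.seed)
    s_ref, s_rest = root.spawn(2)
    if ref is None:
        ref = generate_reference(seed=s_ref)
    germline: dict[str, pd.DataFrame] = {}
    cells: list[CellData] = []
    donor_seeds = s_rest.spawn(len(spec.donors))
    for (donor_id, age), dseed in zip(spec.donors, donor_seeds):
        sub = dseed.spawn(spec.cells_per_donor + 1)
        germline[donor_id] = generate_germline(ref, spec.het_density_per_kb, seed=sub[0])
        for i in range(spec.cells_per_donor):
            cells.append(
                simulate_cell(
                    ref,
                    germline[donor_id],
                    spec.amp_params,
                    spec.ploidy,
                    age,
                    spec.rate_per_mb_per_year,
                    spec.intercept_per_mb,
                    spec.signature_mix,
                    seed=sub[i + 1],
                    cell_id=f"{donor_id}_{spec.cell_type[:2]}{spec.ploidy}n_{i + 1:02d}",
                    donor_id=donor_id,
                    cell_type=spec.cell_type,
                )
            )
    return Cohort(reference=ref, germline=germline, cells=cells, spec=spec)


def generate_annotation(
    ref: ReferenceGenome,
    n_genes: int = 200,
    gene_length: int = 20_000,
    n_exons: int = 3,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic gene models: non-overlapping genes, one transcript each.

    Each gene carries ``n_exons`` CDS intervals (total length a multiple of
    3) inside its transcript span, flanked by UTR and separated by introns.
    Returns (genes, cds) frames in 0-based half-open coordinates.
    """
    rng = _rng(seed)
    genes_rows, cds_rows = [], []
    per_chrom = -(-n_genes // len(ref.chrom_names))
    gid = 0
    for chrom in ref.chrom_names:
        L = ref.chrom_length(chrom)
        slots = np.linspace(1000, L - gene_length - 1000, per_chrom).astype(np.int64)
        for s in slots:
            if gid >= n_genes:
                break
            gid += 1
            gene_id = f"G{gid:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            # jitter the span a little so genes differ in length
            glen = int(gene_length * rng.uniform(0.6, 1.4))
            start, end = int(s), int(s) + glen
            utr = max(200, glen // 10)
            coding_space = glen - 2 * utr
            exon_len = max(30, (coding_space // (2 * n_exons)) // 3 * 3)
            gap = (coding_space - n_exons * exon_len) // max(n_exons - 1, 1)
            pos = start + utr
            for _ in range(n_exons):
                cds_rows.append({"gene_id": gene_id, "start": pos, "end": pos + exon_len})
                pos += exon_len + gap
            genes_rows.append(
                {"gene_id": gene_id, "chrom": chrom, "strand": strand, "start": start, "end": end}
            )
    return pd.DataFrame(genes_rows), pd.DataFrame(cds_rows)


def generate_expression(
    genes: pd.DataFrame, seed: int | np.random.SeedSequence = 0
) -> pd.Series:
    """Log-normal mean expression per gene (arbitrary normalized units)."""
    rng = _rng(seed)
    return pd.Series(
        rng.lognormal(2.0, 1.0, len(genes)), index=genes["gene_id"], name="expression"
    )


def generate_gene_sets(
    genes: pd.DataFrame,
    n_sets: int = 20,
    set_size: int = 25,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, list[str]]:
    """Random opaque gene-id sets (stand-in for ontology terms)."""
    rng = _rng(seed)
    ids = genes["gene_id"].to_numpy()
    return {
        f"SET{i + 1:03d}": list(rng.choice(ids, size=min(set_size, len(ids)), replace=False))
        for i in range(n_sets)
    }
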