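"""Synthetic nrfA amplicon and tracer data with known ground truth.

Emulates the study design the pipeline analyses: five estuarine sediment
sites sequenced with barcoded nrfA amplicons on an Ion-Torrent-style
instrument (~8-bp barcode + degenerate forward primer + ~240 bp of coding
sequence + reverse primer; substitution and homopolymer-length errors), plus
15N tracer slurry incubations with a known true DNRA rate.  Every generator
is seeded and records its ground truth so downstream recovery can be tested
without any external download.

The reference pool stands in for a curated set of NrfA protein fragments
with genus/species labels; genera are simulated as clusters around a genus
ancestor so that within-genus divergence is smaller than between-genus
divergence by construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .isotope_rates import (
    DEFAULT_CARRIER_NMOL,
    DEFAULT_MF_NO3,
    TracerSample,
    TracerSeries,
)

__all__ = [
    "ReferenceEntry",
    "ReferencePool",
    "TrueCommunity",
    "SimulationConfig",
    "FWD_PRIMER",
    "REV_PRIMER",
    "default_barcodes",
    "generate_reference_pool",
    "generate_site_communities",
    "simulate_reads",
    "simulate_tracer_series",
    "generate_geochem_table",
    "write_geochem_table",
    "reverse_translate",
    "resolve_iupac",
    "revcomp",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: one codon per amino acid (the most frequent E. coli codon); only
#: DNA-level error realism matters here, not codon usage bias
CODON = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: heme-motif-targeting degenerate nrfA primer pair
FWD_PRIMER = "CARTGYCAYGTBGARTA"
REV_PRIMER = "TWNGGCATRTGRCARTC"

#: 8-mers with pairwise Hamming distance >= 5
_BARCODES = [
    "ACACACAC", "AGTCGATG", "ATCGTCCA", "CATGCGTT", "CGATAGCT",
    "CTGATTGC", "GACTGCAA", "GCTACTTG", "GTGCAAGT", "TAGCTGGA",
    "TCCAGTAC", "TGTAGCCG",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def resolve_iupac(seq: str, rng: np.random.Generator) -> str:
    """Replace degenerate IUPAC codes with a random compatible base."""
    return "".join(
        b if b in "ACGT" else IUPAC[b][rng.integers(len(IUPAC[b]))] for b in seq
    )


def reverse_translate(protein: str) -> str:
    """Back-translate with the fixed one-codon-per-residue table."""
    try:
        return "".join(CODON[aa] for aa in protein)
    except KeyError as exc:
        raise ValueError(f"cannot back-translate residue {exc}") from exc


def default_barcodes(sites: list[str]) -> dict[str, str]:
    if len(sites) > len(_BARCODES):
        raise ValueError(f"at most {len(_BARCODES)} built-in barcodes available")
    return dict(zip(sites, _BARCODES))


@dataclass(frozen=True)
class ReferenceEntry:
    id: str
    protein: str
    genus: str
    species: str


@dataclass
class ReferencePool:
    """Labelled protein fragments used as taxa and as alignment references."""

    entries: list[ReferenceEntry]

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("reference ids must be unique")
        lengths = {len(e.protein) for e in self.entries}
        if len(lengths) > 1:
            raise ValueError("all reference proteins must have the same length")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    def protein(self, taxon_id: str) -> str:
        return self._by_id()[taxon_id].protein

    def dna(self, taxon_id: str) -> str:
        return reverse_translate(self.protein(taxon_id))

    def _by_id(self) -> dict[str, ReferenceEntry]:
        if not hasattr(self, "_index"):
            self._index = {e.id: e for e in self.entries}
        return self._index

    def genus_of(self, taxon_id: str) -> str:
        return self._by_id()[taxon_id].genus


@dataclass
class TrueCommunity:
    """Ground-truth composition of one site."""

    site_id: str
    members: list[tuple[str, float]]  # (taxon_id, relative abundance)
    endemic_ids: set[str]

    def __post_init__(self) -> None:
        total = sum(a for _, a in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total})")
        member_ids = {t for t, _ in self.members}
        if not self.endemic_ids <= member_ids:
            raise ValueError("endemic_ids must be a subset of member ids")

    @property
    def abundances(self) -> dict[str, float]:
        return dict(self.members)

    def dominant_fraction(self, threshold: float = 0.01) -> float:
        """Summed abundance of taxa individually above ``threshold`` (as %)."""
        return 100.0 * sum(a for _, a in self.members if a > threshold)

    def endemic_fraction(self) -> float:
        """Summed abundance of site-unique taxa (as %)."""
        return 100.0 * sum(a for t, a in self.members if t in self.endemic_ids)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic sequencing experiment."""

    n_sites: int = 5
    depth_per_site: int = 8000
    substitution_rate: float = 0.005  # per base
    homopolymer_indel_rate: float = 0.01  # per homopolymer run (length >= 3)
    #: dispersion of taxon abundances; a scalar, or one value per site —
    #: higher sigma concentrates reads into fewer taxa (tunable dominant fraction)
    lognormal_sigma: float | tuple = 1.5
    endemic_fraction: float = 0.3  # fraction of each site's taxa that are unique
    seed: int = 0
    taxa_per_site: int = 20
    mean_quality: float = 30.0  # per-read mean Phred, Normal(mean, sd)
    quality_sd: float = 4.0
    chimera_rate: float = 0.0  # two-parent splice fraction

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "homopolymer_indel_rate", "endemic_fraction", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth_per_site <= 0:
            raise ValueError("depth_per_site must be > 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        sigmas = self.lognormal_sigma
        if isinstance(sigmas, (int, float)):
            sigmas = (sigmas,)
        elif len(sigmas) != self.n_sites:
            raise ValueError("per-site lognormal_sigma needs one value per site")
        if any(s < 0 for s in sigmas):
            raise ValueError("lognormal_sigma must be >= 0")

    def sigma_for_site(self, index: int) -> float:
        if isinstance(self.lognormal_sigma, (int, float)):
            return float(self.lognormal_sigma)
        return float(self.lognormal_sigma[index])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def generate_reference_pool(
    n_genera: int,
    species_per_genus: int,
    length: int = 80,
    seed: int = 0,
    r_within: float = 0.05,
    r_between: float = 0.3,
) -> ReferencePool:
    """Simulate a genus-structured protein reference set.

    A single ancestor protein is mutated at rate ``r_between`` to obtain each
    genus ancestor, and each genus ancestor at rate ``r_within`` to obtain its
    species, so within-genus identity exceeds between-genus identity by
    construction.
    """
    if n_genera < 1 or species_per_genus < 1:
        raise ValueError("n_genera and species_per_genus must be >= 1")
    if length < 30:
        raise ValueError("length must be >= 30")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))

    def mutate(protein: str, rate: float) -> str:
        chars = np.array(list(protein))
        hits = rng.random(len(chars)) < rate
        for i in np.flatnonzero(hits):
            choices = [c for c in AMINO_ACIDS if c != chars[i]]
            chars[i] = choices[rng.integers(len(choices))]
        return "".join(chars)

    ancestor = "".join(aa[rng.integers(len(aa), size=length)])
    entries = []
    for g in range(n_genera):
        genus_anc = mutate(ancestor, r_between)
        genus = f"G{g + 1:02d}"
        for s in range(species_per_genus):
            protein = mutate(genus_anc, r_within)
            entries.append(
                ReferenceEntry(
                    id=f"{genus}_S{s + 1:02d}",
                    protein=protein,
                    genus=genus,
                    species=f"{genus}_sp{s + 1:02d}",
                )
            )
    return ReferencePool(entries)


def generate_site_communities(
    pool: ReferencePool, config: SimulationConfig
) -> list[TrueCommunity]:
    """Draw per-site communities: shared taxa plus site-unique (endemic) taxa.

    Endemic taxa are allocated to sites disjointly; the remaining pool is
    shared and sampled without replacement per site.  Relative abundances are
    lognormal(sigma) normalised, giving the long-tailed rank-abundance shape
    typical of sediment amplicon libraries.
    """
    if len(pool) == 0:
        raise ValueError("reference pool is empty")
    rng = np.random.default_rng(config.seed)
    k = config.taxa_per_site
    n_endemic = int(round(config.endemic_fraction * k))
    n_shared = k - n_endemic
    need = config.n_sites * n_endemic + n_shared
    if need > len(pool):
        raise ValueError(
            f"pool of {len(pool)} taxa cannot supply {config.n_sites} sites x "
            f"{n_endemic} endemic + {n_shared} shared taxa"
        )
    ids = np.array(pool.ids)
    perm = rng.permutation(len(ids))
    endemic_blocks = [
        set(ids[perm[i * n_endemic : (i + 1) * n_endemic]])
        for i in range(config.n_sites)
    ]
    shared_pool = ids[perm[config.n_sites * n_endemic :]]

    communities = []
    for i in range(config.n_sites):
        site = f"S{i + 1}"
        shared = rng.choice(shared_pool, size=n_shared, replace=False)
        member_ids = sorted(endemic_blocks[i] | set(shared.tolist()))
        sigma = config.sigma_for_site(i)
        if sigma == 0:
            weights = np.ones(len(member_ids))
        else:
            weights = rng.lognormal(mean=0.0, sigma=sigma, size=len(member_ids))
        weights = weights / weights.sum()
        communities.append(
            TrueCommunity(
                site_id=site,
                members=list(zip(member_ids, weights.tolist())),
                endemic_ids=endemic_blocks[i],
            )
        )
    return communities


def _find_homopolymers(seq: str, min_len: int = 3) -> list[tuple[int, int]]:
    """(start, length) of homopolymer runs of at least ``min_len``."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i))
        i = j
    return runs


def _apply_errors(seq: str, config: SimulationConfig, rng: np.random.Generator) -> str:
    # homopolymer-length indels first (operate on the clean run structure)
    if config.homopolymer_indel_rate > 0:
        out = []
        last = 0
        for start, length in _find_homopolymers(seq):
            if rng.random() < config.homopolymer_indel_rate:
                delta = 1 if rng.random() < 0.5 else -1
                out.append(seq[last:start])
                out.append(seq[start] * (length + delta))
                last = start + length
        out.append(seq[last:])
        seq = "".join(out)
    if config.substitution_rate > 0:
        chars = list(seq)
        hits = np.flatnonzero(rng.random(len(chars)) < config.substitution_rate)
        for i in hits:
            alternatives = [b for b in "ACGT" if b != chars[i]]
            chars[i] = alternatives[rng.integers(3)]
        seq = "".join(chars)
    return seq


def simulate_reads(
    communities: list[TrueCommunity],
    pool: ReferencePool,
    config: SimulationConfig,
    fastq_path: str | Path,
    truth_path: str | Path,
    barcodes: dict[str, str] | None = None,
    primers: tuple[str, str] = (FWD_PRIMER, REV_PRIMER),
) -> int:
    """Write an error-bearing FASTQ plus a truth sidecar TSV.

    Each read is ``barcode + forward primer + back-translated taxon DNA +
    reverse-complemented reverse primer`` with substitutions and
    homopolymer-length indels applied, and Phred+33 qualities whose per-read
    mean is Normal(mean_quality, quality_sd) clamped to [2, 40].  Reads are
    emitted in forward orientation only (the barcoded forward primer anchors
    orientation in a single-direction library).  Returns the number of reads
    written.  The truth TSV columns are read_id, site, taxon_id.
    """
    if barcodes is None:
        barcodes = default_barcodes([c.site_id for c in communities])
    _check_barcodes(barcodes, min_distance=3)
    fwd, rev = primers
    rng = np.random.default_rng(config.seed)
    n_written = 0
    with open(fastq_path, "w") as fq, open(truth_path, "w") as truth:
        truth.write("read_id\tsite\ttaxon_id\n")
        for community in communities:
            barcode = barcodes[community.site_id]
            taxa = [t for t, _ in community.members]
            probs = np.array([a for _, a in community.members])
            counts = rng.multinomial(config.depth_per_site, probs)
            taxon_dna = {t: pool.dna(t) for t in taxa}
            read_no = 0
            for taxon, count in zip(taxa, counts):
                for _ in range(count):
                    read_no += 1
                    read_id = f"{community.site_id}_{read_no:06d}"
                    insert = taxon_dna[taxon]
                    true_label = taxon
                    if config.chimera_rate > 0 and rng.random() < config.chimera_rate and len(taxa) > 1:
                        other = taxa[rng.integers(len(taxa))]
                        mid = len(insert) // 2
                        insert = insert[:mid] + taxon_dna[other][mid:]
                        true_label = f"chimera:{taxon}+{other}"
                    dna = (
                        barcode
                        + resolve_iupac(fwd, rng)
                        + insert
                        + revcomp(resolve_iupac(rev, rng))
                    )
                    dna = _apply_errors(dna, config, rng)
                    mean_q = float(np.clip(rng.normal(config.mean_quality, config.quality_sd), 2, 40))
                    quals = np.clip(
                        np.rint(rng.normal(mean_q, 2.0, size=len(dna))), 2, 40
                    ).astype(int)
                    qual_str = "".join(chr(q + 33) for q in quals)
                    fq.write(f"@{read_id}\n{dna}\n+\n{qual_str}\n")
                    truth.write(f"{read_id}\t{community.site_id}\t{true_label}\n")
                    n_written += 1
    return n_written


def _check_barcodes(barcodes: dict[str, str], min_distance: int) -> None:
    items = list(barcodes.items())
    lengths = {len(b) for _, b in items}
    if len(lengths) > 1:
        raise ValueError("barcodes must all have the same length")
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            a, b = items[i][1], items[j][1]
            d = sum(x != y for x, y in zip(a, b))
            if d < min_distance:
                raise ValueError(
                    f"barcodes {a!r} and {b!r} are Hamming distance {d} apart "
                    f"(need >= {min_distance})"
                )


def simulate_tracer_series(
    true_rate: float,
    nh4_pool: float,
    mf_no3: float = DEFAULT_MF_NO3,
    times: list[float] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    carrier_nmol: float = DEFAULT_CARRIER_NMOL,
    site_id: str = "SIM",
) -> TracerSeries:
    """Linear 15NH4 label accumulation at a known true DNRA rate.

    Excess 15NH4 mass grows as ``true_rate * mf_no3 * t`` (nmol 15N g^-1)
    with multiplicative Gaussian noise of relative standard deviation
    ``noise_sd``; the measured mole fraction is diluted by the carrier, so
    the rate estimators (which carrier-correct) invert the simulation exactly
    at ``noise_sd = 0``.
    """
    if nh4_pool <= 0:
        raise ValueError("nh4_pool must be > 0")
    if not 0.0 < mf_no3 <= 1.0:
        raise ValueError("mf_no3 must be in (0, 1]")
    times = list(times)
    if any(t < 0 for t in times) or any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be non-negative and strictly increasing")
    rng = np.random.default_rng(seed)
    samples = []
    for t in times:
        excess = true_rate * mf_no3 * t
        if noise_sd > 0:
            excess *= 1.0 + rng.normal(0.0, noise_sd)
        excess = max(excess, 0.0)
        mf_measured = excess / (nh4_pool + carrier_nmol)
        samples.append(TracerSample(t=t, mf_nh4_measured=mf_measured, nh4_extractable=nh4_pool))
    return TracerSeries(site_id=site_id, samples=samples, mf_no3=mf_no3, carrier_nh4=carrier_nmol)


def ground_truth_from_reads(truth_path: str | Path) -> "pd.DataFrame":
    """Realized per-site dominant/endemic percentages from the truth sidecar.

    Works at the read level, which is what the pipeline estimates: a taxon is
    dominant in a site when it holds > 1% of the site's reads, and endemic
    when its reads occur at exactly one site.  Chimeric reads are excluded
    from taxon attribution.  Columns: site_id, true_pct_dominant,
    true_pct_endemic.
    """
    import pandas as pd

    truth = pd.read_csv(truth_path, sep="\t")
    truth = truth[~truth.taxon_id.str.startswith("chimera:")]
    counts = truth.groupby(["site", "taxon_id"]).size().unstack(fill_value=0)
    frac = counts.div(counts.sum(axis=1), axis=0)
    endemic_taxa = counts.columns[(counts > 0).sum(axis=0) == 1]
    rows = []
    for site in counts.index:
        dom = 100.0 * frac.loc[site, frac.loc[site] > 0.01].sum()
        end = 100.0 * frac.loc[site, endemic_taxa].sum()
        rows.append(
            {"site_id": site, "true_pct_dominant": dom, "true_pct_endemic": end}
        )
    return pd.DataFrame(rows)


#: observed ranges of the printed site geochemistry (min, max) per column
GEOCHEM_RANGES = {
    "salinity_ppt": (9.1, 33.6),
    "bw_no3_uM": (0.25, 0.62),
    "bw_nh4_uM": (0.75, 7.8),
    "pct_organic": (0.33, 18.95),
    "h2s_uM": (0.20, 486.90),
    "nox_uM": (0.23, 0.72),
    "extractable_nh4_umol_g": (0.04, 0.28),
}


def generate_geochem_table(n_sites: int, seed: int = 0):
    """Random site geochemistry within the printed per-column ranges."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    data = {"site_id": [f"S{i + 1}" for i in range(n_sites)]}
    for col, (lo, hi) in GEOCHEM_RANGES.items():
        data[col] = np.round(lo + (hi - lo) * rng.random(n_sites), 2)
    return pd.DataFrame(data)


def write_geochem_table(df, path: str | Path) -> None:
    """Write with fixed formatting so reruns are byte-identical."""
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.2f")
    Path(path).write_text(buf.getvalue())
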