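"""Ancestry-informative marker (AIM) panels.

An AIM panel records, for each SNP, the variant-allele frequency in the two
ancestral populations (here labelled A for the West-African-like and E for the
European-like population), the number of ancestral chromosomes those
frequencies were estimated from, and physical plus genetic map positions.
The frequency *difference* between the two populations is what makes a marker
informative about local ancestry; panels used in practice average an absolute
difference around 0.5-0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PANEL_COLUMNS = ["snp_id", "chrom", "pos_bp", "pos_cM", "freq_A", "freq_E", "n_A", "n_E"]


@dataclass
class AncestralPanel:
    """Per-SNP ancestral allele frequencies with map positions.

    ``table`` holds one row per SNP with columns :data:`PANEL_COLUMNS`,
    sorted by (chrom, pos_bp). Frequencies refer to the *variant* allele;
    ``n_A``/``n_E`` are ancestral panel chromosome counts (2x individuals).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        t = self.table.reset_index(drop=True)
        if len(t):
            if t["snp_id"].duplicated().any():
                dups = t.loc[t["snp_id"].duplicated(), "snp_id"].tolist()
                raise ValueError(f"duplicate snp_id in panel: {dups[:5]}")
            for col in ("freq_A", "freq_E"):
                v = t[col].to_numpy(float)
                if np.any((v < 0) | (v > 1)) or np.any(~np.isfinite(v)):
                    raise ValueError(f"{col} outside [0, 1]")
            if np.any(t[["n_A", "n_E"]].to_numpy() <= 0):
                raise ValueError("panel chromosome counts must be positive")
            t = t.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
            for _, sub in t.groupby("chrom", sort=False):
                cm = sub["pos_cM"].to_numpy(float)
                if np.any(np.diff(cm) < 0):
                    raise ValueError("pos_cM must be non-decreasing within chromosome")
        object.__setattr__(self, "table", t)

    # -- convenience array views -------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_id(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy(int)

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy(int)

    @property
    def pos_cM(self) -> np.ndarray:
        return self.table["pos_cM"].to_numpy(float)

    @property
    def freq_A(self) -> np.ndarray:
        return self.table["freq_A"].to_numpy(float)

    @property
    def freq_E(self) -> np.ndarray:
        return self.table["freq_E"].to_numpy(float)

    @property
    def n_A(self) -> np.ndarray:
        return self.table["n_A"].to_numpy(int)

    @property
    def n_E(self) -> np.ndarray:
        return self.table["n_E"].to_numpy(int)

    def chrom_start_mask(self) -> np.ndarray:
        """Boolean mask, True at the first marker of each chromosome."""
        c = self.chrom
        if len(c) == 0:
            return np.zeros(0, dtype=bool)
        return np.r_[True, c[1:] != c[:-1]]

    def morgan_gaps(self) -> np.ndarray:
        """Genetic distance (Morgans) from the previous marker; 0 at chromosome starts."""
        cm = self.pos_cM
        d = np.zeros(len(cm))
        if len(cm):
            d[1:] = np.diff(cm) / 100.0
            d[self.chrom_start_mask()] = 0.0
        return d

    def index_of(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_id == snp_id)
        if idx.size == 0:
            raise KeyError(f"snp_id {snp_id!r} not in panel")
        return int(idx[0])

    def subset(self, keep: np.ndarray) -> "AncestralPanel":
        """Panel restricted to a boolean mask or integer index array (marker order kept)."""
        return AncestralPanel(self.table.iloc[np.asarray(keep)].reset_index(drop=True))


def rosenberg_informativeness(freq_a, freq_b) -> np.ndarray:
    """Informativeness for assignment (In) of a biallelic marker, two populations.

    In = H(mean frequency) - mean(H(population frequencies)) with H the binary
    entropy in nats; zero when the populations share a frequency, maximal (ln 2)
    for a fixed difference. Used by the ldcheck filter to decide which of two
    redundant markers to keep.
    """
    pa = np.asarray(freq_a, float)
    pb = np.asarray(freq_b, float)

    def h(p):
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -(p * np.log(p) + (1 - p) * np.log(1 - p))

    return h((pa + pb) / 2.0) - (h(pa) + h(pb)) / 2.0


def generate_aim_panel(
    n_snps: int,
    n_chrom: int = 1,
    diff_spec: float = 0.75,
    seed: int = 0,
    spacing_bp: int = 2_000_000,
    n_A: int = 120,
    n_E: int = 120,
) -> AncestralPanel:
    """Generate a synthetic AIM panel.

    Markers are spread evenly over ``n_chrom`` chromosomes at ``spacing_bp``
    intervals with uniform jitter; the genetic map is the 1 cM/Mb desk-scale
    surrogate (pos_cM = pos_bp * 1e-6). Per-SNP frequency differences
    |freq_A - freq_E| are drawn Uniform(diff_spec/2, diff_spec) with random
    sign, so their mean is 0.75*diff_spec >= diff_spec/2; the default
    diff_spec gives a mean difference near 0.56, typical of curated
    African/European AIM panels.

    Parameters
    ----------
    n_snps, n_chrom : panel size; ``n_snps >= n_chrom`` unless ``n_snps == 0``.
    diff_spec : target scale of ancestral frequency differentiation, in (0, 1].
    seed : RNG seed; identical seeds give byte-identical panels.
    spacing_bp : mean physical spacing between adjacent markers.
    n_A, n_E : ancestral panel chromosome counts recorded per SNP.
    """
    if not (0 < diff_spec <= 1):
        raise ValueError(f"diff_spec must be in (0, 1], got {diff_spec}")
    if n_snps < 0:
        raise ValueError("n_snps must be >= 0")
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if 0 < n_snps < n_chrom:
        raise ValueError("need n_snps >= n_chrom")

    if n_snps == 0:
        return AncestralPanel(pd.DataFrame(columns=PANEL_COLUMNS))

    rng = np.random.default_rng(seed)
    # distribute SNP counts across chromosomes as evenly as possible
    per = np.full(n_chrom, n_snps // n_chrom)
    per[: n_snps % n_chrom] += 1

    rows = []
    snp = 0
    for c in range(n_chrom):
        k = per[c]
        base = (np.arange(1, k + 1)) * spacing_bp
        jitter = rng.uniform(-0.3, 0.3, size=k) * spacing_bp
        pos = np.sort(base + jitter).astype(int)
        pos = np.maximum.accumulate(np.maximum(pos, 1))  # keep strictly ordered, >= 1
        pos += np.arange(k)  # break exact ties
        delta = rng.uniform(diff_spec / 2.0, diff_spec, size=k)
        mid = rng.uniform(delta / 2 + 0.01, 1 - delta / 2 - 0.01)
        sign = rng.choice([-1.0, 1.0], size=k)
        fa = mid + sign * delta / 2
        fe = mid - sign * delta / 2
        for j in range(k):
            rows.append(
                (
                    f"rs{c + 1}_{j + 1}",
                    c + 1,
                    int(pos[j]),
                    pos[j] * 1e-6,
                    fa[j],
                    fe[j],
                    n_A,
                    n_E,
                )
            )
        snp += k

    return AncestralPanel(pd.DataFrame(rows, columns=PANEL_COLUMNS))


def generate_ancestral_genotypes(panel: AncestralPanel, seed: int = 0) -> dict:
    """Simulate diploid reference-panel genotypes under Hardy-Weinberg equilibrium.

    Returns ``{"A": matrix, "E": matrix}`` with n/2 individuals x SNPs variant
    counts, drawn Binomial(2, freq) per SNP. These stand in for the ancestral
    genotype data behind the panel frequencies, and let the HWE and LD stages
    of the QC cascade run on fully synthetic input.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for pop, freqs, n in (("A", panel.freq_A, panel.n_A), ("E", panel.freq_E, panel.n_E)):
        n_ind = int(np.min(n)) // 2 if len(panel) else 0
        out[pop] = rng.binomial(2, freqs[None, :], size=(n_ind, len(panel))).astype(np.int8)
    return out
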