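"""Synthetic genomes, expression tables, and GO maps with known truth.

The generators emulate the study design the pipeline targets: promoters
of up to 2 kb upstream of ATG-initiated CDSs carrying zero or one
planted HSE of a chosen class and subunit count, an expression table
over five heat-stress time points in which the probability and
magnitude of a response depend on HSE class, promoter position, and
subunit number, and a term-to-gene map with one optionally planted
enriched term.  Every generator is a pure function of (config, seed)
and returns a ledger of the planted truth so recovery can be asserted.

Planted-HSE ledgers are re-verified by rescanning the generated
promoters: uniform background sequence produces spontaneous HSEs at an
appreciable rate in 2 kb (roughly one per couple of promoters), so the
ledger records what the scanner actually sees rather than assuming the
plant is alone.  ``motif_free_background=True`` rejection-samples
promoters until the planted HSE is the only match, for strict
recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from hsescan import hse_scanner
from hsescan.hse_scanner import KEY_POSITION, _CORE, _FLIP
from hsescan.response_analysis import TIMEPOINTS

CHROMOSOMES = ("chr1A", "chr1B", "chr1D")


@dataclass
class EffectConfig:
    """Generator parameters: genome layout and effect structure.

    The default effect structure is null (no class, position, or
    subunit effect on response probability or magnitude); individual
    effects are switched on per experiment.  Class and subunit-count
    frequencies default to the heavily non-canonical, sharply
    decreasing composition observed in real promoter scans.
    """

    # genome layout
    n_genes: int = 500
    promoter_length: int = 2000
    cds_length: int = 300  # includes the ATG; multiple of 3
    spacer_length: int = 50
    class_probs: dict = field(
        default_factory=lambda: {"typical": 0.05, "gapped": 0.25, "varied": 0.70}
    )
    subunit_probs: dict = field(
        default_factory=lambda: {3: 0.55, 4: 0.25, 5: 0.11, 6: 0.05, 7: 0.03, 8: 0.01}
    )
    frac_no_hse: float = 0.0
    motif_free_background: bool = False
    max_retries: int = 200

    # response probability (log-odds scale)
    baseline_logodds: float = -2.2
    class_logodds: dict = field(
        default_factory=lambda: {"typical": 0.0, "gapped": 0.0, "varied": 0.0}
    )
    position_slope: float = 0.0  # log-odds per bp upstream
    subunit_logodds: dict = field(default_factory=dict)

    # response magnitude (log2 fold-change scale)
    magnitude_mean: float = 2.0
    magnitude_sd: float = 0.6
    magnitude_position_slope: float = 0.0  # log2 per bp
    magnitude_subunit: dict = field(default_factory=dict)
    magnitude_group: dict = field(default_factory=dict)  # "C 2-3" -> offset
    down_fraction: float = 0.2

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticGenome:
    fasta: dict  # seqid -> sequence
    gff3: str
    ledger: pd.DataFrame
    config: EffectConfig
    seed: int

    def write(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "genome.fa",
            "gff3": out / "genes.gff3",
            "ledger": out / "ledger.tsv",
            "config": out / "config.json",
        }
        with open(paths["fasta"], "w") as fh:
            for seqid, seq in self.fasta.items():
                fh.write(f">{seqid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        Path(paths["gff3"]).write_text(self.gff3)
        self.ledger.to_csv(paths["ledger"], sep="\t", index=False)
        Path(paths["config"]).write_text(
            json.dumps({"seed": self.seed, "config": dataclasses.asdict(self.config)},
                       indent=2, sort_keys=True)
        )
        return paths


def build_planted_hse(
    rng: np.random.Generator,
    hse_class: str,
    subunit_count: int,
    first_orientation: Optional[str] = None,
):
    """Construct one HSE sequence of the requested class.

    Returns (sequence, first_orientation, mismatch descriptor or None);
    the sequence satisfies the scanner's admission rules exactly.
    """
    bases = "ACGT"
    if first_orientation is None:
        first_orientation = str(rng.choice(["GAA", "TTC"]))
    orients = []
    o = first_orientation
    for _ in range(subunit_count):
        orients.append(o)
        o = _FLIP[o]
    subunits = []
    for o in orients:
        n1, n5 = rng.choice(list(bases)), rng.choice(list(bases))
        subunits.append(n1 + _CORE[o] + n5)
    mismatch = None
    if hse_class != "typical":
        if hse_class == "gapped":
            # key-position mismatch; middle subunit only when k == 3
            sub_idx = 1 if subunit_count == 3 else int(rng.integers(subunit_count))
            pos = KEY_POSITION[orients[sub_idx]]
        elif hse_class == "varied":
            sub_idx = int(rng.integers(subunit_count))
            nonkey = [p for p in (2, 3, 4) if p != KEY_POSITION[orients[sub_idx]]]
            pos = int(rng.choice(nonkey))
        else:
            raise ValueError(f"unknown HSE class {hse_class!r}")
        canonical = subunits[sub_idx][pos - 1]
        observed = str(rng.choice([b for b in bases if b != canonical]))
        s = subunits[sub_idx]
        subunits[sub_idx] = s[: pos - 1] + observed + s[pos:]
        mismatch = {
            "subunit_index": sub_idx + 1,
            "position_in_subunit": pos,
            "observed_base": observed,
            "is_key": hse_class == "gapped",
        }
    return "".join(subunits), first_orientation, mismatch


def group_label(first_orientation: str, mismatch: Optional[dict]) -> str:
    """Fig-style mismatch group label ('G 2-3'), or 'typical'."""
    if mismatch is None:
        return "typical"
    letter = "G" if first_orientation == "GAA" else "C"
    return f"{letter} {mismatch['subunit_index']}-{mismatch['position_in_subunit']}"


def _random_seq(rng, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _draw_plan(rng, cfg: EffectConfig):
    if cfg.frac_no_hse > 0 and rng.random() < cfg.frac_no_hse:
        return None
    classes = list(cfg.class_probs)
    probs = np.array([cfg.class_probs[c] for c in classes], dtype=float)
    cls = str(rng.choice(classes, p=probs / probs.sum()))
    ks = sorted(cfg.subunit_probs)
    kp = np.array([cfg.subunit_probs[k] for k in ks], dtype=float)
    k = int(rng.choice(ks, p=kp / kp.sum()))
    return cls, k


def _make_promoter(rng, cfg: EffectConfig, plan):
    """Background promoter with an optional planted HSE; returns
    (sequence, plant record or None)."""
    L = cfg.promoter_length
    for _ in range(cfg.max_retries):
        seq = _random_seq(rng, L)
        if plan is None:
            if not cfg.motif_free_background or not hse_scanner.scan_sequence(seq):
                return seq, None
            continue
        cls, k = plan
        hse, orient, mm = build_planted_hse(rng, cls, k)
        offset = int(rng.integers(0, L - 5 * k + 1))
        seq = seq[:offset] + hse + seq[offset + 5 * k :]
        plant = {
            "gene_class": cls,
            "subunit_count": k,
            "offset": offset,
            "distance_to_atg": L - (offset + 5 * k),
            "first_orientation": orient,
            "mismatch_subunit": mm["subunit_index"] if mm else pd.NA,
            "mismatch_position": mm["position_in_subunit"] if mm else pd.NA,
            "mismatch_base": mm["observed_base"] if mm else pd.NA,
            "mismatch_group": group_label(orient, mm),
            "hse_sequence": hse,
        }
        if not cfg.motif_free_background:
            return seq, plant
        found = hse_scanner.scan_sequence(seq)
        if (
            len(found) == 1
            and found[0].start_offset == offset
            and found[0].subunit_count == k
            and found[0].hse_class == cls
        ):
            return seq, plant
    raise RuntimeError(
        f"could not place a clean promoter in {cfg.max_retries} attempts"
    )


def simulate_architecture_ledger(
    cfg: EffectConfig, seed: int, plants: Optional[Sequence[tuple]] = None
) -> pd.DataFrame:
    """Planted-truth ledger without sequences (for statistics-scale runs).

    ``plants`` optionally fixes the (class, subunit_count) per gene;
    otherwise both are drawn from the config distributions.  Positions
    are uniform over the promoter.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(cfg.n_genes):
        gene_id = f"G{i:05d}"
        plan = plants[i] if plants is not None else _draw_plan(rng, cfg)
        if plan is None:
            rows.append({"gene_id": gene_id, "gene_class": "none",
                         "subunit_count": pd.NA, "distance_to_atg": pd.NA,
                         "first_orientation": pd.NA, "mismatch_group": pd.NA})
            continue
        cls, k = plan
        hse, orient, mm = build_planted_hse(rng, cls, k)
        offset = int(rng.integers(0, cfg.promoter_length - 5 * k + 1))
        rows.append(
            {
                "gene_id": gene_id,
                "gene_class": cls,
                "subunit_count": k,
                "distance_to_atg": cfg.promoter_length - (offset + 5 * k),
                "first_orientation": orient,
                "mismatch_group": group_label(orient, mm),
            }
        )
    return pd.DataFrame(rows)


def simulate_genome(
    cfg: EffectConfig, seed: int, plants: Optional[Sequence[tuple]] = None
) -> SyntheticGenome:
    """Genome FASTA + GFF3 with planted HSEs and a verified ledger.

    Genes are laid out in cassettes (promoter, then ATG-initiated CDS,
    then spacer) round-robin across three wheat-style chromosomes,
    alternating strands.  After planting, each promoter is rescanned
    and the ledger records the scanner's view (``rescan_n`` matches,
    ``rescan_exact`` True when the planted HSE is recovered alone).
    """
    if cfg.promoter_length < 5 * max(cfg.subunit_probs):
        raise ValueError("promoter too short for the largest HSE")
    rng = np.random.default_rng(seed)
    chrom_seqs = {c: [] for c in CHROMOSOMES}
    chrom_pos = {c: 0 for c in CHROMOSOMES}
    gff_lines = ["##gff-version 3"]
    rows = []
    for i in range(cfg.n_genes):
        gene_id = f"G{i:05d}"
        seqid = CHROMOSOMES[i % len(CHROMOSOMES)]
        strand = "+" if (i // len(CHROMOSOMES)) % 2 == 0 else "-"
        plan = plants[i] if plants is not None else _draw_plan(rng, cfg)
        promoter, plant = _make_promoter(rng, cfg, plan)
        cds = "ATG" + _random_seq(rng, cfg.cds_length - 3)
        spacer = _random_seq(rng, cfg.spacer_length)
        c0 = chrom_pos[seqid]
        if strand == "+":
            segment = promoter + cds + spacer
            cds_lo = c0 + len(promoter)  # 0-based
            cds_hi = cds_lo + len(cds)
        else:
            segment = reverse_complement(promoter + cds) + spacer
            cds_lo = c0
            cds_hi = c0 + len(cds)
        chrom_seqs[seqid].append(segment)
        chrom_pos[seqid] += len(segment)
        start1, end1 = cds_lo + 1, cds_hi  # GFF3 1-based inclusive
        gff_lines += [
            f"{seqid}\tsynth\tgene\t{start1}\t{end1}\t.\t{strand}\t.\tID={gene_id}",
            f"{seqid}\tsynth\tmRNA\t{start1}\t{end1}\t.\t{strand}\t.\t"
            f"ID={gene_id}.1;Parent={gene_id}",
            f"{seqid}\tsynth\tCDS\t{start1}\t{end1}\t.\t{strand}\t0\t"
            f"ID={gene_id}.1.cds;Parent={gene_id}.1",
        ]
        rescan = hse_scanner.scan_sequence(promoter)
        row = {
            "gene_id": gene_id,
            "seqid": seqid,
            "strand": strand,
            "gene_class": "none",
            "subunit_count": pd.NA,
            "offset": pd.NA,
            "distance_to_atg": pd.NA,
            "first_orientation": pd.NA,
            "mismatch_subunit": pd.NA,
            "mismatch_position": pd.NA,
            "mismatch_base": pd.NA,
            "mismatch_group": pd.NA,
            "hse_sequence": pd.NA,
            "rescan_n": len(rescan),
            "rescan_exact": False,
        }
        if plant is not None:
            row.update(plant)
            row["rescan_exact"] = (
                len(rescan) == 1
                and rescan[0].start_offset == plant["offset"]
                and rescan[0].subunit_count == plant["subunit_count"]
                and rescan[0].hse_class == plant["gene_class"]
            )
        rows.append(row)
    fasta = {c: "".join(parts) for c, parts in chrom_seqs.items() if parts}
    return SyntheticGenome(
        fasta=fasta,
        gff3="\n".join(gff_lines) + "\n",
        ledger=pd.DataFrame(rows),
        config=cfg,
        seed=seed,
    )


def simulate_response_truth(
    ledger: pd.DataFrame, cfg: EffectConfig, seed: int, organ: str = "leaves"
) -> pd.DataFrame:
    """Per-gene response flag and magnitude implied by the effect model.

    Response: Bernoulli(logistic(baseline + class offset + position
    slope * position + subunit offset)).  Magnitude: log2 maximal fold
    change ~ Normal(mean + group/subunit/position terms, sd), truncated
    below at 1 so every responsive gene clears the two-fold threshold;
    ``mfh`` is the within-organ z-score of max_fc over responsive genes.
    """
    rng = np.random.default_rng(seed)
    n = len(ledger)
    cls = ledger["gene_class"].to_numpy()
    pos = pd.to_numeric(ledger["distance_to_atg"], errors="coerce").fillna(0.0).to_numpy(dtype=float)
    subs = pd.to_numeric(ledger["subunit_count"], errors="coerce").to_numpy(dtype=float)
    groups = ledger["mismatch_group"].astype(object).fillna("none").to_numpy()

    logodds = np.full(n, cfg.baseline_logodds, dtype=float)
    for c, off in cfg.class_logodds.items():
        logodds[cls == c] += off
    logodds += cfg.position_slope * pos
    for k, off in cfg.subunit_logodds.items():
        logodds[subs == k] += off
    prob = 1.0 / (1.0 + np.exp(-logodds))
    responsive = rng.random(n) < prob

    mu = np.full(n, cfg.magnitude_mean, dtype=float)
    mu += cfg.magnitude_position_slope * pos
    for k, off in cfg.magnitude_subunit.items():
        mu[subs == k] += off
    for g, off in cfg.magnitude_group.items():
        mu[groups == g] += off
    log2max = np.maximum(rng.normal(mu, cfg.magnitude_sd), 1.0)
    down = rng.random(n) < cfg.down_fraction

    truth = pd.DataFrame(
        {
            "gene_id": ledger["gene_id"].to_numpy(),
            "organ": organ,
            "gene_class": cls,
            "position": pos,
            "subunit_count": ledger["subunit_count"].to_numpy(),
            "mismatch_group": groups,
            "responsive": responsive,
            "log2_max_fc": log2max,
            "down_regulated": down,
        }
    )
    truth["max_fc"] = np.where(responsive, 2.0 ** log2max, np.nan)
    resp = truth["responsive"].to_numpy()
    if resp.sum() >= 2:
        x = truth.loc[resp, "max_fc"]
        truth.loc[resp, "mfh"] = (x - x.mean()) / x.std(ddof=1)
    else:
        truth["mfh"] = np.nan
    return truth


def simulate_expression(
    ledger: pd.DataFrame,
    cfg: EffectConfig,
    seed: int,
    organ: str = "leaves",
    timepoints: Sequence[str] = TIMEPOINTS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential-expression table encoding the simulated truth.

    Responsive genes carry their maximal fold change (down-regulated
    ones as its reciprocal) with adjusted p < 0.05 at one peak time
    point and sub-threshold values elsewhere; non-responsive genes stay
    strictly inside (1/2, 2) at every time point, so threshold calling
    recovers the true flags exactly.  Returns (de_table, truth).
    """
    truth = simulate_response_truth(ledger, cfg, seed, organ=organ)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    n = len(truth)
    tps = list(timepoints)
    peak = rng.integers(0, len(tps), size=n)
    rows = []
    for i, rec in enumerate(truth.itertuples(index=False)):
        for j, tp in enumerate(tps):
            if rec.responsive and j == peak[i]:
                fc = 2.0 ** rec.log2_max_fc
                if rec.down_regulated:
                    fc = 1.0 / fc
                p = rng.uniform(1e-8, 0.049)
            else:
                fc = 2.0 ** rng.uniform(-0.9, 0.9)
                p = rng.uniform(0.0, 1.0)
            rows.append((rec.gene_id, organ, tp, fc, p))
    de = pd.DataFrame(
        rows, columns=["gene_id", "organ", "timepoint", "fold_change", "adj_p"]
    )
    return de, truth


def simulate_annotation(
    gene_ids: Sequence[str],
    n_terms: int,
    planted_term: Optional[set] = None,
    seed: int = 0,
    term_size_range: tuple[int, int] = (10, 50),
) -> tuple[dict, Optional[str]]:
    """Random GO-style term map with one optionally planted term.

    Returns ({term_id: gene set}, planted term id).  The planted term
    contains exactly the supplied genes.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    gene_ids = list(gene_ids)
    if planted_term is not None and not set(planted_term) <= set(gene_ids):
        raise ValueError("planted term genes must be drawn from gene_ids")
    rng = np.random.default_rng(seed)
    term_map = {}
    for t in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        size = min(size, len(gene_ids))
        members = rng.choice(gene_ids, size=size, replace=False)
        term_map[f"GO:{t + 1:07d}"] = set(map(str, members))
    planted_id = None
    if planted_term is not None:
        planted_id = f"GO:{n_terms + 1:07d}"
        term_map[planted_id] = set(planted_term)
    return term_map, planted_id


def write_term_map(term_map: dict, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(term_map):
            for gene in sorted(term_map[term]):
                fh.write(f"{term}\t{gene}\n")
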