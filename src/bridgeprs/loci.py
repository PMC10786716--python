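"""Locus definition by greedy clumping, and per-locus genotypic covariance.

A locus is a lead variant plus every variant within a distance window whose
squared correlation with the lead, in a reference panel, exceeds a threshold.
Loci are disjoint: once a variant is assigned it leaves the candidate pool,
so downstream models can treat loci as independent blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .formats_io import GenotypePanel, SumStats

logger = logging.getLogger("bridgeprs")


@dataclass
class Locus:
    locus_id: str
    lead: str                 # variant id of the lead SNP
    members: list             # ordered variant ids, lead included
    top_pval: float           # smallest p among members in the defining GWAS
    span: tuple               # (chrom, start_pos, end_pos), 1-based inclusive


@dataclass
class LDBlock:
    locus: Locus
    phi: np.ndarray           # genotypic covariance among members (0-2 dosage units)
    freq_panel: np.ndarray    # panel allele frequency per member


def clump(s: SumStats, panel: GenotypePanel, p1: float = 0.01, p2: float = 0.01,
          kb: int = 1000, r2: float = 0.01) -> list[Locus]:
    """Greedy clumping of summary statistics against a reference panel.

    Repeatedly takes the unassigned variant with the smallest p-value at most
    ``p1`` as a lead (ties broken by smallest (chrom, pos)), and assigns to it
    every unassigned variant with p <= ``p2``, within ``kb`` kilobases of the
    lead, whose squared panel correlation with the lead exceeds ``r2``. The
    panel must be harmonized to ``s`` (same variants, same order, same
    orientation). Returns possibly-empty list; no variant with p > p2 is ever
    assigned.
    """
    if len(s) != len(panel.variants) or s.keys != panel.keys:
        raise ValueError("panel must be harmonized to the summary statistics "
                         "(same variants in the same order)")
    p = s.pval
    chrom = s.table["chrom"].to_numpy(str)
    pos = s.table["pos"].to_numpy(int)
    ids = s.table["id"].to_numpy(str)

    X = panel.dosages - panel.dosages.mean(axis=0)
    norms = np.sqrt((X ** 2).sum(axis=0))
    norms[norms == 0] = np.nan  # monomorphic: correlation undefined -> excluded

    candidate = p <= p2
    unassigned = candidate.copy()
    # lead order: by (p, chrom, pos); numeric chroms sort numerically
    def _chrom_sort(c):
        return (0, int(c)) if c.isdigit() else (1, c)
    order = sorted(np.nonzero(p <= p1)[0],
                   key=lambda i: (p[i], _chrom_sort(chrom[i]), pos[i]))

    loci: list[Locus] = []
    for lead_idx in order:
        if not unassigned[lead_idx]:
            continue
        in_window = (unassigned
                     & (chrom == chrom[lead_idx])
                     & (np.abs(pos - pos[lead_idx]) <= kb * 1000))
        cand = np.nonzero(in_window)[0]
        with np.errstate(invalid="ignore"):
            r = (X[:, cand].T @ X[:, lead_idx]) / (norms[cand] * norms[lead_idx])
        members_idx = cand[np.nan_to_num(r) ** 2 > r2]
        if lead_idx not in members_idx:  # lead always belongs to its own locus
            members_idx = np.append(members_idx, lead_idx)
        members_idx = members_idx[np.argsort(pos[members_idx], kind="stable")]
        unassigned[members_idx] = False
        loci.append(Locus(
            locus_id=f"locus_{len(loci) + 1}_{ids[lead_idx]}",
            lead=ids[lead_idx],
            members=list(ids[members_idx]),
            top_pval=float(p[members_idx].min()),
            span=(chrom[lead_idx], int(pos[members_idx].min()),
                  int(pos[members_idx].max())),
        ))
    logger.info("clump: %d loci from %d variants (p1=%g, p2=%g, kb=%d, r2=%g)",
                len(loci), len(s), p1, p2, kb, r2)
    return loci


def compute_phi(locus: Locus, panel: GenotypePanel, jitter: float = 0.0) -> LDBlock:
    """Allele-aligned genotypic covariance of a locus from a reference panel.

    phi is the mean-centered dosage covariance (ddof=0, so that n*phi equals
    the centered cross-product exactly) plus ``jitter`` on the diagonal;
    freq_panel is mean dosage / 2. phi may be rank-deficient; the posterior's
    prior precision keeps the downstream system invertible.
    """
    panel_pos = {v: j for j, v in enumerate(panel.variants["id"])}
    missing = [m for m in locus.members if m not in panel_pos]
    if missing:
        raise KeyError(f"locus {locus.locus_id}: members absent from panel: "
                       f"{missing}")
    idx = [panel_pos[m] for m in locus.members]
    X = panel.dosages[:, idx]
    Xc = X - X.mean(axis=0)
    phi = (Xc.T @ Xc) / X.shape[0]
    phi = 0.5 * (phi + phi.T)  # enforce exact symmetry
    if jitter:
        phi = phi + jitter * np.eye(phi.shape[0])
    return LDBlock(locus=locus, phi=phi, freq_panel=X.mean(axis=0) / 2.0)


def write_loci(loci: list[Locus], path) -> None:
    """Serialize a locus set as tab-delimited locus_id/lead/member/top_pval."""
    with open(path, "w") as fh:
        fh.write("locus_id\tlead_id\tmember_id\ttop_pval\n")
        for loc in loci:
            for m in loc.members:
                fh.write(f"{loc.locus_id}\t{loc.lead}\t{m}\t{loc.top_pval:.6g}\n")
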