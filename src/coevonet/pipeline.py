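"""End-to-end family analysis: alignment → tensor → per-protein energetics,
networks, frustration and temporal trends.

The run is driven by a :class:`RunConfig` (loadable from a flat
``key = value`` text file) whose defaults are the analysis constants: 30 %
gap filter, 70 % identity reweighting, pseudocounts 0.5/0.1/1.0, 6.5 Å
contact cutoff, 5 % null quantile for the strongly-attractive threshold.
Outputs are tidy TSV tables plus a JSON provenance record; runs are
deterministic given the config seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_io import (
    AlignmentMatrix,
    compute_weights,
    filter_gap_fraction,
    read_alignment,
    read_metadata,
)
from .coevolution import CouplingTensor, PseudocountConfig, count_frequencies, infer_couplings
from .energetics import project_energies, site_energy_profile
from .frustration import scaling_exponent
from .networks import (
    attractive_fraction,
    build_network,
    calibrate_threshold,
    frustrated_fraction,
    network_stats,
    site_frustration_profile,
)
from .null_models import null_contact_energies, random_graph_null
from .structure import ContactMap, contact_map_from_structure, filter_to_native
from .trends import age_binned_profile, trend_table

log = logging.getLogger("coevonet")

TREND_QUANTITIES = ["E_N", "a", "f", "alpha", "lcs", "orphan_fraction", "clustering"]


@dataclass
class RunConfig:
    """Paths and parameters of one family analysis."""

    alignment: str = ""
    dated_sequences: str = ""
    dated_metadata: str = ""
    contact_map: str = ""
    structure: str = ""
    output_dir: str = "results"
    family: str = "family"
    # analysis constants (defaults are the standard published values)
    max_gap: float = 0.30
    identity_threshold: float = 0.70
    mutual_gap: float = 0.20
    pc_x: float = 0.5
    pc_y: float = 0.1
    pc_z: float = 1.0
    cutoff: float = 6.5
    min_separation: int = 2
    null_quantile: float = 0.05
    null_replicates: int = 1
    null_projections: int = 0  # 0 = project every bootstrapped sequence
    graph_null_replicates: int = 200
    n_boot: int = 100_000
    seed: int = 0
    fit_lo: int = 0  # 0 = automatic pre-drop linear region
    fit_hi: int = 0

    @property
    def pseudocounts(self) -> PseudocountConfig:
        return PseudocountConfig(x=self.pc_x, y=self.pc_y, z=self.pc_z)

    @property
    def fit_range(self) -> tuple[int, int] | None:
        if self.fit_lo and self.fit_hi:
            return (self.fit_lo, self.fit_hi)
        return None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` config file ('#' starts a comment)."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for line_no, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{line_no}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{line_no}: unknown config key {key!r}")
            caster = {"str": str, "float": float, "int": int}[fields[key]]
            kwargs[key] = caster(value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")


def load_contact_map(config: RunConfig, n_expected: int | None = None) -> ContactMap:
    if config.contact_map:
        return ContactMap.read_tsv(config.contact_map)
    if config.structure:
        return contact_map_from_structure(
            config.structure,
            cutoff=config.cutoff,
            min_separation=config.min_separation,
            n_expected=n_expected,
        )
    raise ValueError("config must provide contact_map or structure")


def per_protein_table(
    tensor: CouplingTensor,
    dated: AlignmentMatrix,
    cm: ContactMap,
    eps_th: float,
    fit_range: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, list, list]:
    """Tidy per-protein results plus the E_i and f_i site profiles.

    Columns: protein id, age, E_N, fractions a and f, frustration exponent
    alpha with its fit range, attractive-network LCS/orphans/clustering and
    the same statistics for the frustrated network.
    """
    if dated.ages is None:
        raise ValueError(f"every protein needs an age; missing for all of {dated.ids[:3]}")
    from .energetics import native_energy

    rows, e_profiles, f_profiles = [], [], []
    for k, pid in enumerate(dated.ids):
        em = project_energies(tensor, dated.matrix[k], cm, protein_id=pid, age=dated.ages[k])
        att = network_stats(build_network(em, "attractive", eps_th))
        fru = network_stats(build_network(em, "frustrated"))
        scaling = scaling_exponent(em, fit_range=fit_range)
        rows.append(
            {
                "protein_id": pid,
                "age_My": float(dated.ages[k]),
                "E_N": native_energy(em),
                "a": attractive_fraction(em, eps_th),
                "f": frustrated_fraction(em),
                "alpha": scaling.alpha,
                "fit_lo": scaling.fit_range[0],
                "fit_hi": scaling.fit_range[1],
                "lcs": att["lcs"],
                "orphan_fraction": att["orphan_fraction"],
                "clustering": att["clustering"],
                "frustrated_lcs": fru["lcs"],
                "frustrated_orphans": fru["orphan_fraction"],
                "frustrated_clustering": fru["clustering"],
            }
        )
        e_profiles.append(site_energy_profile(em, eps_th))
        f_profiles.append(site_frustration_profile(em))
    return pd.DataFrame(rows), e_profiles, f_profiles


def run_family_analysis(config: RunConfig) -> dict:
    """Run the complete analysis; returns the output tables in memory and
    writes them under ``config.output_dir``.

    Steps: read and gap-filter the family alignment; reweight; infer the
    coupling tensor; filter to native contacts; calibrate ε_th on
    column-bootstrap null energies; project every dated protein; compute
    per-protein statistics, age-binned site profiles, random-graph null
    references and per-quantity trend tests.
    """
    rng = np.random.default_rng(config.seed)
    aln = read_alignment(config.alignment)
    aln = filter_gap_fraction(aln, config.max_gap)
    weights = compute_weights(aln, config.identity_threshold)
    log.info(
        "family=%s M=%d M_eff=%.1f N=%d", config.family, aln.n_sequences,
        weights.m_eff, aln.n_columns,
    )
    cm = load_contact_map(config, n_expected=aln.n_columns)
    log.info("native contacts: %d (cutoff %.2f Å)", cm.n_contacts, config.cutoff)

    freqs = count_frequencies(aln, weights, config.pseudocounts)
    tensor = filter_to_native(infer_couplings(freqs, family=config.family), cm)

    pools = [
        null_contact_energies(
            aln,
            cm,
            pc=config.pseudocounts,
            identity_threshold=config.identity_threshold,
            n_projections=config.null_projections or None,
            seed=rng,
        )
        for _ in range(config.null_replicates)
    ]
    null_pool = np.concatenate(pools)
    eps_th = calibrate_threshold(null_pool, config.null_quantile)
    log.info("eps_th=%.4f from %d pooled null energies", eps_th, null_pool.size)

    dated = read_alignment(config.dated_sequences)
    meta = read_metadata(config.dated_metadata)
    missing = sorted(set(dated.ids) - set(meta["id"]))
    if missing:
        raise ValueError(f"proteins without an age in the metadata: {missing}")
    dated = dated.with_metadata(meta)

    results, e_profiles, f_profiles = per_protein_table(
        tensor, dated, cm, eps_th, config.fit_range
    )

    mean_edges = int(round(results["a"].mean() * cm.n_contacts))
    graph_null = random_graph_null(
        cm.n_residues, max(mean_edges, 1), config.graph_null_replicates, rng
    )

    if config.n_boot > 0:
        trends = trend_table(
            results, TREND_QUANTITIES, n_boot=config.n_boot, seed=config.seed
        )
    else:
        warnings.warn("n_boot = 0: trend p-values reported as NA", stacklevel=2)
        trends = trend_table(results, TREND_QUANTITIES, n_boot=0, seed=config.seed)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "per_protein.tsv", sep="\t", index=False, float_format="%.10g")
    trends.to_csv(out / "trends.tsv", sep="\t", index=False, float_format="%.10g")
    age_binned_profile(e_profiles).to_csv(
        out / "site_energy_profiles.tsv", sep="\t", index=False, float_format="%.10g"
    )
    age_binned_profile(f_profiles).to_csv(
        out / "site_frustration_profiles.tsv", sep="\t", index=False, float_format="%.10g"
    )
    graph_null.describe().loc[["mean", "std"]].to_csv(out / "graph_null.tsv", sep="\t")
    summary = {
        "family": config.family,
        "M": aln.n_sequences,
        "M_eff": weights.m_eff,
        "N": aln.n_columns,
        "n_contacts": cm.n_contacts,
        "eps_th": eps_th,
        "null_pool_size": int(null_pool.size),
        "seed": config.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    config.to_file(out / "config.txt")
    return {
        "results": results,
        "trends": trends,
        "eps_th": eps_th,
        "null_pool": null_pool,
        "graph_null": graph_null,
        "summary": summary,
        "tensor": tensor,
    }
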