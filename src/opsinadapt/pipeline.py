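"""End-to-end orchestration of the opsin-adaptation analysis.

``run_pipeline`` chains the stages — synthetic-data generation (or user
FASTA input), allele grouping and frequencies, mean Ds/Dn, the HKA panel,
pairwise FST, the NJ allele tree with bootstrap, and A1/A2 spectral
unmixing — writing CSV/newick outputs plus a JSON run manifest.  Identical
config and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alleles import allele_frequencies, group_alleles, site_table
from .core import Alignment, Haplotype
from .divergence import mean_ds_dn
from .hka import RegionCounts, hka_panel, region_counts
from .phylo import bootstrap_support
from .popgen import fst_matrix, min_fst_partner
from .simulate import (
    SimSequenceParams,
    SimSpectrumParams,
    simulate_coding_alleles,
    simulate_spectrum,
    simulate_two_region_data,
)
from .spectra import estimate_lambda_max, fit_a1_a2_mixture


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run (YAML-serializable)."""

    seed: int = 1
    # synthetic coding data
    n_allele_groups: int = 6
    haplotypes_per_group: int = 4
    codon_count: int = 120
    aa_diffs_between_groups: int = 3
    syn_diffs_within_group: int = 2
    # HKA stage
    theta: float = 5.0
    divergence_time: float = 2.0
    n_ingroup: int = 20
    region_lengths: tuple[int, int] = (2000, 2000)
    divergence_inflation: tuple[float, float] = (1.0, 1.0)
    region_names: tuple[str, str] = ("up", "gene")
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    # spectra stage
    lambda_max_a1: float = 544.0
    lambda_max_a2: float = 595.0
    a2_fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    spectrum_noise_sd: float = 0.005
    phi_step: float = 0.01
    smoothing_window_nm: float = 5.0
    # tree stage
    bootstrap_reps: int = 200
    # optional user inputs (paths); when set they replace the synthetic stage
    input_fasta: str | None = None
    metadata_csv: str | None = None
    cds_start: int = 1
    cds_end: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)

    def validate(self) -> None:
        if self.n_ingroup < 2:
            raise ValueError("n_ingroup must be >= 2")
        if len(self.region_lengths) != len(self.region_names):
            raise ValueError("region_lengths and region_names lengths differ")
        for path in (self.input_fasta, self.metadata_csv):
            if path is not None and not Path(path).exists():
                raise ValueError(f"referenced file does not exist: {path}")


def validate_regions(regions: list[tuple[str, int, int]]) -> None:
    """Reject overlapping 1-based inclusive region intervals."""
    ordered = sorted(regions, key=lambda r: r[1])
    for (n1, _, e1), (n2, s2, _) in zip(ordered, ordered[1:]):
        if s2 <= e1:
            raise ValueError(f"regions {n1!r} and {n2!r} overlap")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every analysis stage and write outputs under ``outdir``.

    Returns a manifest dict (also written as ``manifest.json``) naming each
    stage's output file.  A stage failure raises with the stage named;
    outputs of completed stages remain on disk.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "outputs": {},
    }

    def _stage(name):
        def wrap(fn):
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # ------------------------------------------------------------ alleles
    @_stage("alleles")
    def _alleles():
        aln, truth = simulate_coding_alleles(
            config.n_allele_groups, config.haplotypes_per_group,
            config.codon_count, config.aa_diffs_between_groups,
            config.syn_diffs_within_group, seed=int(rng.integers(2 ** 31)))
        species = [f"sp{int(i) + 1}" for i in
                   rng.integers(0, 3, size=aln.n)]
        haps = [Haplotype(i, s, species=sp)
                for (i, s), sp in zip(aln, species)]
        groups, failures = group_alleles(haps)
        assign = pd.DataFrame(
            [{"haplotype": m, "allele": g.label, "true_group": truth[m]}
             for g in groups for m in g.member_ids])
        _write_csv(assign.sort_values("haplotype").reset_index(drop=True),
                   outdir / "allele_assignments.csv")
        _write_csv(site_table(aln), outdir / "site_table.csv")
        _write_csv(allele_frequencies(groups, haps, "species"),
                   outdir / "allele_frequencies.csv")
        manifest["outputs"]["alleles"] = [
            "allele_assignments.csv", "site_table.csv", "allele_frequencies.csv"]
        # dsdn on the same coding alignment
        res = mean_ds_dn(aln)
        _write_csv(pd.DataFrame([{
            "mean_ds": res.ds, "mean_dn": res.dn,
            "syn_sites": res.syn_sites, "nonsyn_sites": res.nonsyn_sites,
            "pairs_used": res.pairs_used,
            "pairs_undefined": res.pairs_undefined,
        }]), outdir / "dsdn.csv")
        manifest["outputs"]["dsdn"] = ["dsdn.csv"]

    # ---------------------------------------------------------------- hka
    @_stage("hka")
    def _hka():
        params = SimSequenceParams(
            theta_per_region=config.theta,
            divergence_time=config.divergence_time,
            n_ingroup=config.n_ingroup,
            region_lengths=tuple(config.region_lengths),
            divergence_inflation=tuple(config.divergence_inflation),
            seed=int(rng.integers(2 ** 31)))
        aligns, outs = simulate_two_region_data(params)
        counts = [region_counts(a, o, name)
                  for a, o, name in zip(aligns, outs, config.region_names)]
        panel = hka_panel(counts, alpha_levels=tuple(config.alpha_levels))
        _write_csv(panel, outdir / "hka_panel.csv")
        manifest["outputs"]["hka"] = ["hka_panel.csv"]

    # ---------------------------------------------------------------- fst
    @_stage("fst")
    def _fst():
        pops: dict[str, Alignment] = {}
        for k, pname in enumerate(("popA", "popB", "popC")):
            params = SimSequenceParams(
                theta_per_region=config.theta, divergence_time=0.0,
                n_ingroup=max(config.n_ingroup // 2, 2),
                region_lengths=(config.region_lengths[0],),
                divergence_inflation=(1.0,),
                seed=int(rng.integers(2 ** 31)))
            aligns, _ = simulate_two_region_data(params)
            aln = aligns[0]
            pops[pname] = Alignment(
                [f"{pname}_{i}" for i in aln.ids], aln.seqs)
        pairs = fst_matrix(pops)
        _write_csv(pd.DataFrame([{
            "pop1": p.pop1, "pop2": p.pop2, "fst": p.fst,
            "hw": p.hw, "hb": p.hb, "negative": p.negative,
        } for p in pairs]), outdir / "fst_matrix.csv")
        partner, fst = min_fst_partner("popA", pops)
        _write_csv(pd.DataFrame([{"focal": "popA", "partner": partner,
                                  "fst": fst}]),
                   outdir / "fst_min_partner.csv")
        manifest["outputs"]["fst"] = ["fst_matrix.csv", "fst_min_partner.csv"]

    # --------------------------------------------------------------- tree
    @_stage("tree")
    def _tree():
        aln, _ = simulate_coding_alleles(
            6, 1, 400, aa_diffs_between_groups=6,
            seed=int(rng.integers(2 ** 31)))
        tree = bootstrap_support(aln, reps=config.bootstrap_reps,
                                 seed=int(rng.integers(2 ** 31)))
        (outdir / "allele_tree.nwk").write_text(str(tree))
        manifest["outputs"]["tree"] = ["allele_tree.nwk"]

    # ------------------------------------------------------------ spectra
    @_stage("spectra")
    def _spectra():
        t_a1 = simulate_spectrum(SimSpectrumParams(
            config.lambda_max_a1, config.lambda_max_a2, 0.0, 0.0))
        t_a2 = simulate_spectrum(SimSpectrumParams(
            config.lambda_max_a1, config.lambda_max_a2, 1.0, 0.0))
        rows = []
        for phi in config.a2_fractions:
            obs = simulate_spectrum(SimSpectrumParams(
                config.lambda_max_a1, config.lambda_max_a2, float(phi),
                config.spectrum_noise_sd, seed=int(rng.integers(2 ** 31))))
            lmax, se = estimate_lambda_max([obs])
            fit = fit_a1_a2_mixture(
                t_a1, t_a2, observed=obs, mode="curve-match",
                phi_step=config.phi_step)
            rows.append({
                "true_a2_fraction": phi, "observed_lambda_max": lmax,
                "lambda_max_se": se,
                "fitted_a2_fraction": fit.a2_fraction,
                "fitted_lambda_max": fit.lambda_max,
                "residual": fit.residual,
            })
        _write_csv(pd.DataFrame(rows), outdir / "a1a2_unmixing.csv")
        manifest["outputs"]["spectra"] = ["a1a2_unmixing.csv"]

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
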