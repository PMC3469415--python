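"""Statsmodels-style front end: `InfluenceModel` and `InfluenceResults`.

`InfluenceModel` holds an aligned genotype/phenotype dataset; `fit()`
runs the full inference pipeline:

    standardize -> eigentrait SVD -> single-locus scan -> covariate
    selection -> all pairwise interaction fits -> activity changes ->
    directed influences -> tandem-permutation empirical p-values ->
    Holm adjustment -> cross-model averaging of variant-to-phenotype
    effects -> significance-filtered network

and returns an `InfluenceResults` carrying coefficient tables,
propagated standard errors, adjusted p-values, the network, and a
`summary()`.  All randomness flows from one master seed; per-pair child
streams are derived from locus identifiers, so results are independent
of pair processing order and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .eigentraits import EigentraitDecomposition, decompose, standardize
from .influences import (COND_MAX, DENOM_TOL, influence_coefficients,
                         solve_activity_changes)
from .io import GenotypeMatrix, PhenotypeTable, align_samples
from .network import average_effects, build_network, write_network
from .scans import pairwise_fit, select_covariates, single_locus_scan
from .significance import (empirical_pvalue, holm_adjust, pairwise_null,
                           single_locus_threshold)

__all__ = ["InfluenceModel", "InfluenceResults"]


class InfluenceModel:
    """Directed genetic influence model for a genotyped population.

    Parameters
    ----------
    genotypes : GenotypeMatrix or DataFrame (samples x loci, values in [0, 1])
    phenotypes : PhenotypeTable or DataFrame (samples x >=2 phenotypes)
    decompose : if True (default) phenotypes are standardized and rotated
        to eigentraits before scanning, and effect estimates are
        recomposed onto the original phenotypes afterwards (lossless).
        Pass False when the columns are already orthogonal composite
        phenotypes (e.g. expression SVD modes).
    """

    def __init__(self, genotypes, phenotypes, decompose: bool = True):
        if not isinstance(genotypes, GenotypeMatrix):
            genotypes = GenotypeMatrix(pd.DataFrame(genotypes))
        if not isinstance(phenotypes, PhenotypeTable):
            phenotypes = PhenotypeTable(pd.DataFrame(phenotypes))
        if not phenotypes.pleiotropy_available:
            raise ValueError(
                "influence inference needs >=2 phenotypes (partial pleiotropy)"
            )
        self.genotypes, self.phenotypes = align_samples(genotypes, phenotypes)
        self._decompose = decompose

    @classmethod
    def from_files(cls, genotype_path, phenotype_path, **kwargs) -> "InfluenceModel":
        from .io import read_genotypes, read_phenotypes
        return cls(read_genotypes(genotype_path), read_phenotypes(phenotype_path),
                   **kwargs)

    @property
    def locus_ids(self) -> list:
        return self.genotypes.locus_ids

    def fit(self, covariate_threshold: float = 3.55, n_perm_pair: int = 100000,
            alpha: float = 0.05, seed: int = 0, cond_max: float = COND_MAX,
            denom_tol: float = DENOM_TOL, calibrate_threshold: bool = False,
            n_perm_single: int = 10000, threshold_alpha: float = 0.01
            ) -> "InfluenceResults":
        """Run the full pipeline and return an `InfluenceResults`.

        ``covariate_threshold`` (default 3.55, the permutation-calibrated
        p<0.01 cutoff) selects strong-effect variants; pass
        ``calibrate_threshold=True`` to recompute it for this design from
        ``n_perm_single`` genotype permutations via a fitted extreme value
        distribution.  ``n_perm_pair`` tandem permutations per pair build
        the empirical nulls (default 100,000; >=1,000 is a reasonable
        desk-scale setting).  ``alpha`` filters the final network on
        Holm-adjusted p-values.
        """
        if self._decompose:
            Pstd = standardize(self.phenotypes)
            dec = decompose(Pstd)
            Y = dec.U
            phen_ids = list(map(str, dec.phenotype_ids))
        else:
            dec = None
            Y = self.phenotypes.values
            if np.isnan(Y).any():
                raise ValueError("missing phenotype values")
            phen_ids = list(map(str, self.phenotypes.phenotype_ids))
        k = Y.shape[1]

        scan = single_locus_scan(self.genotypes, Y)
        evd = None
        thr = covariate_threshold
        if calibrate_threshold:
            evd = single_locus_threshold(self.genotypes, Y, n_perm=n_perm_single,
                                         alpha=threshold_alpha, seed=seed)
            thr = evd.threshold
        covariates = select_covariates(scan, thr)

        loci = self.locus_ids
        pairs = list(itertools.combinations(loci, 2))
        fits, activities, ipairs = {}, {}, {}
        vp_obs = {}       # pair -> (coef (2, m), var (2, m))
        skipped = []
        for pair in pairs:
            fit = pairwise_fit(self.genotypes, Y, pair, covariates)
            fits[pair] = fit
            if not fit.estimable:
                skipped.append((pair, fit.note))
                continue
            ac = solve_activity_changes(fit, cond_max=cond_max)
            activities[pair] = ac
            ipairs[pair] = influence_coefficients(ac, denom_tol=denom_tol)
            bmain = np.stack([fit.beta1, fit.beta2])             # (2, k)
            vmain = np.stack([fit.cov3[:, 0, 0], fit.cov3[:, 1, 1]])
            if dec is not None:
                M = dec.S[:, None] * dec.Vt
                vp_obs[pair] = (bmain @ M, vmain @ M**2)
            else:
                vp_obs[pair] = (bmain, vmain)

        # tandem-permutation nulls, one child stream per pair
        nulls = {}
        for pair in pairs:
            if pair not in ipairs:
                continue
            nulls[pair] = pairwise_null(self.genotypes, Y, pair, covariates,
                                        n_perm=n_perm_pair, seed=seed, dec=dec,
                                        cond_max=cond_max, denom_tol=denom_tol)

        # raw empirical p for the influence (gamma) coefficients
        gamma_keys, gamma_raw = [], []
        for pair, ip in ipairs.items():
            ip.p_raw = np.full(2, np.nan)
            ip.p_adj = np.full(2, np.nan)
            for d in range(2):
                if ip.valid[d] and np.isfinite(ip.stat[d]):
                    null_d = nulls[pair].gamma_stat[:, d]
                    if np.isnan(null_d).all():
                        continue
                    gamma_keys.append((pair, d))
                    gamma_raw.append(empirical_pvalue(ip.stat[d], null_d))

        # averaged variant-to-phenotype effects + matched permutation nulls
        per_model: dict = {}
        contrib: dict = {}
        for pair, (coef, var) in vp_obs.items():
            for pos, variant in enumerate(pair):
                for m, phen in enumerate(phen_ids):
                    per_model.setdefault((str(variant), phen), []).append(
                        (coef[pos, m], var[pos, m]))
                contrib.setdefault(str(variant), []).append((pair, pos))
        effects = average_effects(per_model)
        eff_raw = []
        for eff in effects:
            plist = contrib[eff.variant]
            m_idx = phen_ids.index(eff.phenotype)
            cmat = np.stack([nulls[pair].vp_coef[:, pos, m_idx] for pair, pos in plist])
            vmat = np.stack([nulls[pair].vp_var[:, pos, m_idx] for pair, pos in plist])
            with np.errstate(invalid="ignore", divide="ignore"):
                null_mean = cmat.mean(axis=0)
                null_se = np.sqrt(vmat.mean(axis=0)) / np.sqrt(len(plist))
                null_stat = np.abs(null_mean) / null_se
            eff.p_raw = empirical_pvalue(eff.stat, null_stat)
            eff_raw.append(eff.p_raw)

        # one Holm family over every coefficient that can become a network
        # edge, so the step-down controls the family-wise error of the
        # network as a whole under arbitrary dependence
        all_raw = gamma_raw + eff_raw
        if all_raw:
            adj = holm_adjust(all_raw)
            for (pair, d), pr, pa in zip(gamma_keys, gamma_raw, adj[:len(gamma_raw)]):
                ipairs[pair].p_raw[d] = pr
                ipairs[pair].p_adj[d] = float(pa)
            for eff, pa in zip(effects, adj[len(gamma_raw):]):
                eff.p_adj = float(pa)

        net = build_network(list(ipairs.values()), effects, alpha=alpha)
        if skipped:
            warnings.warn(
                f"{len(skipped)} pair(s) skipped: "
                + "; ".join(f"{p}: {note}" for p, note in skipped),
                stacklevel=2,
            )

        config = {
            "covariate_threshold": float(thr),
            "threshold_calibrated": bool(calibrate_threshold),
            "n_perm_pair": int(n_perm_pair),
            "n_perm_single": int(n_perm_single) if calibrate_threshold else None,
            "alpha": float(alpha),
            "seed": int(seed),
            "cond_max": float(cond_max),
            "denom_tol": float(denom_tol),
            "decompose": bool(self._decompose),
            "version": __version__,
        }
        return InfluenceResults(
            model=self, config=config, decomposition=dec, single_locus=scan,
            covariates=covariates, fits=fits, activities=activities,
            influence_pairs=ipairs, effects=effects, network=net,
            evd_threshold=evd, skipped_pairs=skipped,
            null_invalid={p: n.n_invalid for p, n in nulls.items()},
            phenotype_ids=phen_ids,
        )


@dataclass
class InfluenceResults:
    """Fitted influence network with estimates, errors and diagnostics."""

    model: InfluenceModel
    config: dict
    decomposition: EigentraitDecomposition | None
    single_locus: pd.DataFrame
    covariates: object
    fits: dict
    activities: dict
    influence_pairs: dict
    effects: list
    network: object
    evd_threshold: object = None
    skipped_pairs: list = field(default_factory=list)
    null_invalid: dict = field(default_factory=dict)
    phenotype_ids: list = field(default_factory=list)

    # ---- tables ---------------------------------------------------------
    def influences_table(self) -> pd.DataFrame:
        rows = []
        for pair, ip in self.influence_pairs.items():
            ac = self.activities[pair]
            l1, l2 = map(str, pair)
            for d, (src, dst) in enumerate([(l2, l1), (l1, l2)]):
                rows.append({
                    "source": src, "target": dst, "gamma": ip.gamma[d],
                    "se": ip.se[d], "stat": ip.stat[d],
                    "p_raw": ip.p_raw[d] if ip.p_raw is not None else np.nan,
                    "p_adj": ip.p_adj[d] if ip.p_adj is not None else np.nan,
                    "valid": bool(ip.valid[d]), "solve_mode": ac.solve_mode,
                    "condition": ac.condition, "resid_norm": ac.residual_norm,
                })
        return pd.DataFrame(rows)

    def effects_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "variant": e.variant, "phenotype": e.phenotype, "coef": e.coef,
            "se": e.se, "n_models": e.n_models, "stat": e.stat,
            "p_raw": e.p_raw, "p_adj": e.p_adj,
        } for e in self.effects])

    def pairwise_table(self) -> pd.DataFrame:
        rows = []
        for pair, fit in self.fits.items():
            if not fit.estimable:
                rows.append({"locus1": str(pair[0]), "locus2": str(pair[1]),
                             "estimable": False, "note": fit.note})
                continue
            for j in range(fit.k):
                se12 = np.sqrt(fit.cov3[j, 2, 2])
                rows.append({
                    "locus1": str(pair[0]), "locus2": str(pair[1]),
                    "eigentrait": j + 1, "beta1": fit.beta1[j],
                    "beta2": fit.beta2[j], "beta12": fit.beta12[j],
                    "se12": se12,
                    "stat12": abs(fit.beta12[j]) / se12 if se12 > 0 else np.inf,
                    "n_used": fit.n_used, "estimable": True, "note": "",
                })
        return pd.DataFrame(rows)

    # ---- presentation ---------------------------------------------------
    def summary(self) -> str:
        g = self.model.genotypes
        lines = [
            "Directed Genetic Influence Model",
            "=" * 60,
            f"samples: {len(g.sample_ids)}   loci: {len(g.locus_ids)}   "
            f"phenotypes: {len(self.phenotype_ids)}",
            f"seed: {self.config['seed']}   pairwise permutations: "
            f"{self.config['n_perm_pair']}   alpha: {self.config['alpha']}",
            f"covariate threshold: {self.config['covariate_threshold']:.3g}"
            + (" (EVD-calibrated)" if self.config["threshold_calibrated"] else ""),
        ]
        for j, cov in sorted(self.covariates.per_trait.items()):
            lines.append(f"covariates ET{j + 1}: {cov if cov else '(none)'}")
        if self.skipped_pairs:
            lines.append(f"skipped pairs: {self.skipped_pairs}")
        lines += ["", "Variant-to-variant influences (negative = suppression)",
                  "-" * 60,
                  self.influences_table().to_string(index=False, float_format="%.4g")]
        lines += ["", "Averaged variant-to-phenotype effects", "-" * 60,
                  self.effects_table().to_string(index=False, float_format="%.4g")]
        lines += ["", f"network: {self.network.n_edges} significant edge(s) "
                      f"at adjusted p < {self.network.alpha}"]
        return "\n".join(lines)

    # ---- persistence ----------------------------------------------------
    def save(self, outdir) -> None:
        """Write the results bundle (fixed file names) to ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if self.decomposition is not None:
            dec = self.decomposition
            pd.DataFrame(dec.U, index=dec.sample_ids,
                         columns=dec.eigentrait_ids).to_csv(
                out / "eigentraits.tsv", sep="\t", index_label="sample")
            pd.DataFrame(dec.Vt, index=dec.eigentrait_ids,
                         columns=dec.phenotype_ids).assign(
                singular_value=dec.S).to_csv(
                out / "eigentrait_loadings.tsv", sep="\t", index_label="eigentrait")
        self.single_locus.to_csv(out / "single_locus.tsv", sep="\t", index=False)
        self.pairwise_table().to_csv(out / "pairwise.tsv", sep="\t", index=False)
        self.influences_table().to_csv(out / "influences.tsv", sep="\t", index=False)
        self.effects_table().to_csv(out / "effects.tsv", sep="\t", index=False)
        write_network(self.network, out / "network.graphml", "graphml")
        write_network(self.network, out / "network.tsv", "tsv")
        run = dict(self.config)
        run["covariates"] = {f"ET{j + 1}": v
                             for j, v in self.covariates.per_trait.items()}
        run["null_invalid_permutations"] = {str(k): v
                                            for k, v in self.null_invalid.items()}
        run["network_note"] = self.network.metadata.get("note", "")
        (out / "run.json").write_text(json.dumps(run, indent=2))
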