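"""Synthetic multi-modal cohort generator.

Emulates the statistical structure the response-prediction pipeline assumes,
without attempting photorealistic histology or CT appearance:

* a per-patient latent risk ``z ~ N(0, 1)`` (higher = worse prognosis);
* pathology tiles: textured eosin-like background with dark "nuclei" blobs
  whose density and contrast increase with ``z * effect_image``;
* radiology lesion ROIs: a bright ellipse on a noisy background whose
  diameter and internal heterogeneity increase with ``z * effect_image``,
  plus the matching binary mask and an organ code obeying RECIST caps;
* structured reports: peritoneal-metastasis probability rises with
  ``effect_report * z`` and the TIL level falls with it;
* patient information: differentiation/Lauren odds shift with
  ``effect_info * z``;
* outcomes: PFS is exponential with rate
  ``pfs_hazard_scale * exp(risk_coef * z)`` where ``risk_coef`` is the mean
  of the three effect strengths, so a zero-effect cohort is a true null
  (labels independent of z); OS adds an exponential tail; an independent
  exponential censoring clock yields roughly 20% censoring at defaults;
  RECIST categories are sampled from logits linear in ``risk_coef * z``.

Modality availability follows ``frac_both / frac_path_only / frac_rad_only``
(defaults mirror a cohort where fewer than half of patients have both
modalities). Everything is deterministic for a fixed seed. Ground truth
(latent risk, realised responder labels) goes to a sidecar JSON never read
by training code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image

from . import data_model as dm

__all__ = ["SimConfig", "GroundTruth", "generate_cohort", "impose_missingness",
           "write_cohort"]


@dataclass
class SimConfig:
    """Generator settings; defaults are the package's reference conditions."""

    n_patients: int = 400
    seed: int = 0
    frac_both: float = 0.45
    frac_path_only: float = 0.30
    frac_rad_only: float = 0.25
    effect_image: float = 2.5
    effect_report: float = 2.0
    effect_info: float = 1.5
    base_response_rate: float = 0.5
    pfs_hazard_scale: float | None = None  # derived from base_response_rate if None
    image_size: int = 64
    bags_per_patient: int = 4
    words_per_bag: int = 4
    lesions_per_patient: int = 2
    cohort: str = "antiHER2"

    def validate(self) -> None:
        total = self.frac_both + self.frac_path_only + self.frac_rad_only
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"availability fractions sum to {total}, expected 1")
        for name in ("effect_image", "effect_report", "effect_info"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 1 <= self.lesions_per_patient <= dm.MAX_LESIONS_TOTAL:
            raise ValueError("lesions_per_patient must respect the RECIST cap")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    @property
    def risk_coef(self) -> float:
        """Strength of the latent-risk -> outcome link (mean effect size)."""
        return (self.effect_image + self.effect_report + self.effect_info) / 3.0

    @property
    def hazard_scale(self) -> float:
        """Baseline PFS hazard per month. When ``pfs_hazard_scale`` is None it
        is calibrated so a z=0 patient exceeds the cohort PFS threshold with
        probability ``base_response_rate``."""
        if self.pfs_hazard_scale is not None:
            return self.pfs_hazard_scale
        thr = dm.responder_threshold(self.cohort)
        return -math.log(self.base_response_rate) / thr


@dataclass
class GroundTruth:
    """Sidecar truth for a generated cohort (never used in training)."""

    latent_risk: list[float]
    true_label: list[str]  # label_responder output per patient

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh)


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _pathology_tile(rng: np.random.Generator, size: int, signal: float) -> np.ndarray:
    """Eosin-like background with dark nuclei; density/contrast rise with signal."""
    base = np.array([0.85, 0.70, 0.82])
    img = np.ones((size, size, 3)) * base
    # smooth texture whose amplitude grows with the planted signal
    noise = rng.normal(0.0, 1.0, size=(size // 4, size // 4))
    noise = np.kron(noise, np.ones((4, 4)))
    amp = 0.03 + 0.05 * _sigmoid(signal)
    img += amp * noise[..., None]
    n_blobs = rng.poisson(8 + 22 * _sigmoid(signal))
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(2, size - 2, size=2)
        r = rng.uniform(1.5, 3.0)
        blob = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * r ** 2)))
        img -= blob[..., None] * np.array([0.45, 0.55, 0.25])
    return np.clip(img, 0.0, 1.0)


def _radiology_lesion(rng: np.random.Generator, size: int,
                      signal: float) -> tuple[np.ndarray, np.ndarray]:
    """Bright elliptic lesion on noisy background; diameter and internal
    heterogeneity rise with signal. Returns (image, mask)."""
    img = rng.normal(0.30, 0.05, size=(size, size))
    ry = size * (0.18 + 0.12 * _sigmoid(signal)) * rng.uniform(0.85, 1.15)
    rx = size * (0.18 + 0.12 * _sigmoid(signal)) * rng.uniform(0.85, 1.15)
    cy = size / 2 + rng.uniform(-2, 2)
    cx = size / 2 + rng.uniform(-2, 2)
    yy, xx = np.mgrid[0:size, 0:size]
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    hetero = 0.02 + 0.10 * _sigmoid(signal)
    lesion = 0.70 + rng.normal(0.0, hetero, size=(size, size))
    img = np.where(mask, lesion, img)
    return np.clip(img, 0.0, 1.0), mask


def _sample_recist(rng: np.random.Generator, u: float) -> str:
    """RECIST category from logits linear in the scaled latent risk u."""
    base = np.log([0.10, 0.35, 0.35, 0.20])  # CR, PR, SD, PD at u = 0
    direction = np.array([-1.0, -0.5, 0.3, 1.0])
    logits = base + direction * u
    p = np.exp(logits - logits.max())
    p /= p.sum()
    return str(rng.choice(np.array(dm.RECIST), p=p))


def _sample_info(rng: np.random.Generator, u_info: float) -> dm.PatientInfo:
    def tilted(vocab, base, tilt):
        w = np.asarray(base) * np.exp(np.asarray(tilt) * u_info)
        w /= w.sum()
        return str(rng.choice(np.array(vocab), p=w))

    def tri(vocab, p_na=0.25):
        if rng.random() < p_na:
            return "NA"
        return str(rng.choice(np.array(vocab[:2])))

    return dm.PatientInfo(
        age=float(np.clip(round(rng.normal(60, 9)), 18, 100)),
        sex="male" if rng.random() < 0.7 else "female",
        tumor_site="GEJ" if rng.random() < 0.35 else "nonGEJ",
        differentiation=tilted(dm.DIFFERENTIATION, [0.40, 0.40, 0.20],
                               [0.8, 0.0, -0.8]),
        lauren=tilted(dm.LAUREN[:3], [0.45, 0.35, 0.20], [-0.6, 0.6, 0.0])
        if rng.random() > 0.15 else "NA",
        treatment_line=int(rng.integers(1, 4)),
        days_to_treatment=float(np.round(rng.uniform(0, 60), 1)),
        pdl1=tri(dm.TRI_STATE),
        mmr=tri(dm.MMR),
        ebv=tri(dm.TRI_STATE),
        tnm_stage="IV" if rng.random() < 0.75 else "III",
    )


def _sample_rad_report(rng: np.random.Generator, u_rep: float) -> dm.RadReport:
    n_ln = int(min(rng.poisson(2.0 * math.exp(0.25 * u_rep)), 20))
    if n_ln > 0:
        k = int(min(1 + rng.poisson(0.8), len(dm.LN_SITES), n_ln))
        locs = sorted(rng.choice(np.array(dm.LN_SITES), size=k, replace=False).tolist())
    else:
        locs = []
    return dm.RadReport(
        post_gastrectomy=bool(rng.random() < 0.30),
        n_met_lymph_nodes=n_ln,
        ln_locations=locs,
        liver_met=bool(rng.random() < _sigmoid(-1.2 + 0.3 * u_rep)),
        lung_met=bool(rng.random() < 0.15),
        peritoneal_met=bool(rng.random() < _sigmoid(-1.5 + u_rep)),
        ln_type_diversity=len(locs),
    )


def _sample_path_report(rng: np.random.Generator, u_rep: float) -> dm.PathReport:
    til = float(np.clip(0.35 + rng.normal(0, 0.08) - 0.12 * np.tanh(u_rep), 0.0, 1.0))
    her2 = {"3+"}
    for lvl in ("0", "1+", "2+"):
        if rng.random() < 0.35:
            her2.add(lvl)
    return dm.PathReport(
        tumor_proportion=float(np.clip(rng.beta(4, 2), 0.0, 1.0)),
        til_level=round(til, 4),
        her2_heterogeneity=sorted(her2, key=dm.HER2_LEVELS.index),
    )


_LESION_ORGAN_POOL = ("stomach", "liver", "lymph_node", "peritoneum", "lung",
                      "spleen", "bone", "soft_tissue")


def generate_cohort(config: SimConfig, out_dir: str | Path,
                    write_images: bool = True
                    ) -> tuple[list[dm.PatientRecord], GroundTruth]:
    """Generate a cohort under ``config``; image assets are written as PNGs
    under ``out_dir`` and referenced by relative path in the records.

    Deterministic for a fixed seed (byte-identical manifests and PNGs).
    """
    config.validate()
    out_dir = Path(out_dir)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    z = rng.standard_normal(n)
    avail = rng.choice(3, size=n, p=[config.frac_both, config.frac_path_only,
                                     config.frac_rad_only])
    scale = config.hazard_scale
    thr = dm.responder_threshold(config.cohort)

    records: list[dm.PatientRecord] = []
    truths_z: list[float] = []
    truths_label: list[str] = []
    if write_images:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)

    for i in range(n):
        pid = f"P{i:04d}"
        zi = float(z[i])
        u_img = config.effect_image * zi
        u_rep = config.effect_report * zi
        u_inf = config.effect_info * zi
        u_out = config.risk_coef * zi

        has_path = avail[i] in (0, 1)
        has_rad = avail[i] in (0, 2)

        path_report = path_assets = None
        if has_path:
            path_report = _sample_path_report(rng, u_rep)
            path_assets = []
            tile = _pathology_tile(rng, config.image_size, u_img)
            rel = f"images/{pid}_path0.png"
            if write_images:
                Image.fromarray((tile * 255).round().astype(np.uint8)).save(
                    out_dir / rel)
            path_assets.append(rel)

        rad_report = rad_assets = None
        if has_rad:
            rad_report = _sample_rad_report(rng, u_rep)
            rad_assets = []
            organs = ["stomach"] + [
                _LESION_ORGAN_POOL[1 + int(rng.integers(0, 5))]
                for _ in range(config.lesions_per_patient - 1)]
            # enforce the per-organ cap deterministically
            seen: dict[str, int] = {}
            fixed = []
            for organ in organs:
                if seen.get(organ, 0) >= dm.MAX_LESIONS_PER_ORGAN:
                    organ = next(o for o in _LESION_ORGAN_POOL
                                 if seen.get(o, 0) < dm.MAX_LESIONS_PER_ORGAN)
                seen[organ] = seen.get(organ, 0) + 1
                fixed.append(organ)
            for j, organ in enumerate(fixed):
                img, mask = _radiology_lesion(rng, config.image_size // 2, u_img)
                rel_img = f"images/{pid}_rad{j}.png"
                rel_mask = f"images/{pid}_rad{j}_mask.png"
                if write_images:
                    Image.fromarray((img * 255).round().astype(np.uint8)).save(
                        out_dir / rel_img)
                    Image.fromarray((mask * 255).astype(np.uint8)).save(
                        out_dir / rel_mask)
                rad_assets.append((rel_img, rel_mask, organ))

        recist = _sample_recist(rng, u_out)
        pfs_raw = rng.exponential(1.0 / (scale * math.exp(u_out)))
        censor = rng.exponential(1.0 / (0.25 * scale))
        pfs = min(pfs_raw, censor)
        pfs_event = pfs_raw <= censor
        os_raw = pfs_raw + rng.exponential(6.0)
        outcome = dm.Outcome(
            recist=recist,
            pfs_months=round(pfs, 3),
            pfs_event=bool(pfs_event),
            os_months=round(min(os_raw, censor), 3),
            os_event=bool(os_raw <= censor),
        )
        rec = dm.PatientRecord(
            patient_id=pid, cohort=config.cohort,
            info=_sample_info(rng, u_inf), outcome=outcome,
            rad_report=rad_report, path_report=path_report,
            pathology_assets=path_assets, radiology_assets=rad_assets,
        )
        rec.validate()
        records.append(rec)
        truths_z.append(zi)
        truths_label.append(dm.label_responder(outcome, config.cohort))

    return records, GroundTruth(latent_risk=truths_z, true_label=truths_label)


def write_cohort(config: SimConfig, out_dir: str | Path) -> Path:
    """Generate and persist a cohort: manifest, assets and truth sidecar.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    records, truth = generate_cohort(config, out_dir)
    manifest = out_dir / "manifest.jsonl"
    dm.write_manifest(records, manifest)
    truth.save(out_dir / "ground_truth.json")
    return manifest


def impose_missingness(records: list[dm.PatientRecord], frac_path_only: float,
                       frac_rad_only: float, seed: int
                       ) -> list[dm.PatientRecord]:
    """Strip exactly one modality from randomly selected patients.

    ``frac_path_only`` of patients lose radiology, ``frac_rad_only`` lose
    pathology (disjoint selections, reproducible by seed). No patient ever
    loses both; if the requested fractions cannot be met without that, a
    ValueError is raised. Returns new records; inputs are not mutated.
    """
    if not (0 <= frac_path_only <= 1 and 0 <= frac_rad_only <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if frac_path_only + frac_rad_only >= 1 + 1e-12:
        raise ValueError("fractions must sum to less than 1")
    n = len(records)
    n_po = int(round(frac_path_only * n))
    n_ro = int(round(frac_rad_only * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    lose_rad: set[int] = set()
    lose_path: set[int] = set()
    for idx in order:
        rec = records[idx]
        if len(lose_rad) < n_po and rec.has_pathology and rec.has_radiology:
            lose_rad.add(idx)
        elif len(lose_path) < n_ro and rec.has_pathology and rec.has_radiology:
            lose_path.add(idx)
    if len(lose_rad) < n_po or len(lose_path) < n_ro:
        raise ValueError(
            "requested missingness fractions would force a patient to lose "
            "both modalities")
    out = []
    for idx, rec in enumerate(records):
        from dataclasses import replace
        if idx in lose_rad:
            rec = replace(rec, rad_report=None, radiology_assets=None)
        elif idx in lose_path:
            rec = replace(rec, path_report=None, pathology_assets=None)
        out.append(rec)
    return out
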