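"""Adversarial MR-to-CT translation: three model variants and their training.

Variants
--------
``GAN``
    one generator + one discriminator, trained with paired slices on an
    L1 (MAE) term and a least-squares adversarial term at ratio 15:1.
``CYCGAN``
    two generators + two discriminators, unpaired training with the
    cycle-consistency loss and the adversarial loss at ratio 10:1.
``RGGAN``
    the CycGAN formulation plus a reference MAE term against the paired
    (registered) CT, weight 100 — reference-guided CycGAN.

The LSGAN objectives are, for the CT-domain discriminator,
``E_x(D_CT(x) - 1)^2 + E_y(D_CT(G_MRI(y)))^2`` (plus the mirrored MR-domain
terms for the cycle variants) and for the generators
``E_y(D_CT(G_MRI(y)) - 1)^2`` (plus the mirrored term).  All losses operate
in normalized [-1, 1] units; HU-scale errors are only reported after
denormalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from . import nn
from .grid import Modality, VolumeGrid
from .preprocess import NormalizationSpec, crop_or_pad_array, denormalize_ct, resample_volume


class Variant(str, Enum):
    GAN = "gan"
    CYCGAN = "cycgan"
    RGGAN = "rggan"


class TrainingDiverged(RuntimeError):
    def __init__(self, record: "LossRecord"):
        super().__init__(f"non-finite loss at iteration {record.iteration}: {record}")
        self.record = record


@dataclass
class LossWeights:
    """Weighted-sum coefficients of the training objectives."""

    gan_mae_to_adv: float = 15.0  # paired L1 : adversarial, plain GAN
    cyc_cycle_to_adv: float = 10.0  # cycle : adversarial, CycGAN/RgGAN
    rg_reference_weight: float = 100.0  # paired L1 weight, RgGAN

    def __post_init__(self) -> None:
        if min(self.gan_mae_to_adv, self.cyc_cycle_to_adv) <= 0 or self.rg_reference_weight < 0:
            raise ValueError("loss weights must be positive")


@dataclass
class TrainConfig:
    """Optimizer and schedule settings (full-scale defaults)."""

    batch_size: int = 2
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    epochs_constant: int = 10  # lr held constant
    epochs_decay: int = 30  # then linear decay to 0
    crop_rows_cols: tuple[int, int] = (356, 356)
    seed: int = 0

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch index; 0 after the schedule ends."""
        if epoch < 1:
            raise ValueError("epochs are 1-based")
        if epoch <= self.epochs_constant:
            return self.learning_rate
        done = epoch - self.epochs_constant
        if done >= self.epochs_decay:
            return 0.0
        return self.learning_rate * (1.0 - done / self.epochs_decay)

    @property
    def total_epochs(self) -> int:
        return self.epochs_constant + self.epochs_decay


def desk_train_config(seed: int = 0, epochs_constant: int = 2, epochs_decay: int = 6,
                      crop: tuple[int, int] = (76, 76)) -> TrainConfig:
    """Reduced-scale preset: 8 epochs with the 1:3 constant-to-decay split and
    the full-scale optimizer settings."""
    return TrainConfig(
        epochs_constant=epochs_constant, epochs_decay=epochs_decay,
        crop_rows_cols=crop, seed=seed,
    )


@dataclass
class LossRecord:
    iteration: int
    adv_dis: float
    adv_gen: float
    cycle: float | None
    reference_mae: float | None
    total: float

    def is_finite(self) -> bool:
        vals = [self.adv_dis, self.adv_gen, self.total]
        vals += [v for v in (self.cycle, self.reference_mae) if v is not None]
        return bool(np.all(np.isfinite(vals)))


@dataclass
class ModelBundle:
    """Generators and discriminators of one variant plus build metadata."""

    variant: Variant
    g_mri: nn.Layer  # MR -> CT
    d_ct: nn.Layer
    g_ct: nn.Layer | None = None  # CT -> MR (cycle variants only)
    d_mri: nn.Layer | None = None
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        two_sided = self.variant is not Variant.GAN
        if two_sided and (self.g_ct is None or self.d_mri is None):
            raise ValueError(f"{self.variant.value} needs two generators and two discriminators")
        if not two_sided and (self.g_ct is not None or self.d_mri is not None):
            raise ValueError("plain GAN has exactly one generator and one discriminator")

    def parameter_counts(self) -> dict[str, int]:
        out = {"g_mri": nn.n_parameters(self.g_mri), "d_ct": nn.n_parameters(self.d_ct)}
        if self.g_ct is not None:
            out["g_ct"] = nn.n_parameters(self.g_ct)
            out["d_mri"] = nn.n_parameters(self.d_mri)
        return out

    def generator_params(self) -> list[nn.Parameter]:
        p = list(self.g_mri.params())
        if self.g_ct is not None:
            p += self.g_ct.params()
        return p

    def discriminator_params(self) -> list[nn.Parameter]:
        p = list(self.d_ct.params())
        if self.d_mri is not None:
            p += self.d_mri.params()
        return p

    # -- checkpointing ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        import json

        path = Path(path)
        arrays = {}
        for name, net in (("g_mri", self.g_mri), ("g_ct", self.g_ct),
                          ("d_ct", self.d_ct), ("d_mri", self.d_mri)):
            if net is None:
                continue
            for i, p in enumerate(net.params()):
                arrays[f"{name}.{i}"] = p.value
        np.savez(path.with_suffix(".npz"), **arrays)
        manifest = {"variant": self.variant.value, "scale": self.scale, "seed": self.seed}
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        import json

        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        bundle = build_models(Variant(manifest["variant"]), manifest["scale"], manifest["seed"])
        data = np.load(path.with_suffix(".npz"))
        for name, net in (("g_mri", bundle.g_mri), ("g_ct", bundle.g_ct),
                          ("d_ct", bundle.d_ct), ("d_mri", bundle.d_mri)):
            if net is None:
                continue
            for i, p in enumerate(net.params()):
                p.value[...] = data[f"{name}.{i}"]
        return bundle


def architecture_for_scale(scale: float) -> tuple[int, int]:
    """(base width, residual blocks).  scale 1 matches the printed parameter
    counts (11.3 M generator / 2.7 M discriminator within 5%)."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if scale >= 1:
        return 64, 9
    return max(4, int(round(64 * scale))), max(2, int(round(9 * scale)))


def build_models(variant: Variant | str, scale: float = 1.0, seed: int = 0) -> ModelBundle:
    """Construct a freshly initialized bundle; deterministic given the seed."""
    variant = Variant(variant)
    base, blocks = architecture_for_scale(scale)
    rng = np.random.default_rng(seed)
    g_mri = nn.resnet_generator(base, blocks, rng=rng)
    d_ct = nn.patch_discriminator(base, rng=rng)
    g_ct = d_mri = None
    if variant is not Variant.GAN:
        g_ct = nn.resnet_generator(base, blocks, rng=rng)
        d_mri = nn.patch_discriminator(base, rng=rng)
    return ModelBundle(variant, g_mri, d_ct, g_ct, d_mri, scale=scale, seed=seed)


# ---------------------------------------------------------------------------
# loss closed forms (scalars from score maps / images)


def lsgan_discriminator_loss(
    real_scores: np.ndarray,
    fake_scores: np.ndarray,
    variant: Variant | str = Variant.GAN,
    real_scores_mr: np.ndarray | None = None,
    fake_scores_mr: np.ndarray | None = None,
) -> float:
    """Least-squares discriminator objective (two terms; four for cycle variants)."""
    variant = Variant(variant)
    total = float(np.mean((np.asarray(real_scores) - 1.0) ** 2)) + float(
        np.mean(np.asarray(fake_scores) ** 2)
    )
    if variant is not Variant.GAN:
        if real_scores_mr is None or fake_scores_mr is None:
            raise ValueError("cycle variants need MR-domain score maps")
        total += float(np.mean((np.asarray(real_scores_mr) - 1.0) ** 2)) + float(
            np.mean(np.asarray(fake_scores_mr) ** 2)
        )
    return total


def lsgan_generator_loss(
    fake_scores: np.ndarray,
    variant: Variant | str = Variant.GAN,
    fake_scores_mr: np.ndarray | None = None,
) -> float:
    """Least-squares generator objective (one term; two for cycle variants)."""
    variant = Variant(variant)
    total = float(np.mean((np.asarray(fake_scores) - 1.0) ** 2))
    if variant is not Variant.GAN:
        if fake_scores_mr is None:
            raise ValueError("cycle variants need the MR-domain score map")
        total += float(np.mean((np.asarray(fake_scores_mr) - 1.0) ** 2))
    return total


def cycle_loss(
    original: np.ndarray,
    reconstructed: np.ndarray,
    original_mr: np.ndarray | None = None,
    reconstructed_mr: np.ndarray | None = None,
) -> float:
    """Mean absolute reconstruction error, averaged over the cycle directions given."""
    a, b = np.asarray(original), np.asarray(reconstructed)
    if a.shape != b.shape:
        raise ValueError("cycle_loss shape mismatch")
    out = float(np.mean(np.abs(a - b)))
    if original_mr is not None:
        c, d = np.asarray(original_mr), np.asarray(reconstructed_mr)
        if c.shape != d.shape:
            raise ValueError("cycle_loss shape mismatch")
        out = 0.5 * (out + float(np.mean(np.abs(c - d))))
    return out


def reference_mae_loss(sct_slice: np.ndarray, ct_slice: np.ndarray) -> float:
    """Mean absolute error between a generated and a paired reference slice."""
    return float(np.mean(np.abs(np.asarray(sct_slice) - np.asarray(ct_slice))))


def total_loss(
    variant: Variant | str,
    adv_gen: float,
    cycle: float | None = None,
    reference_mae: float | None = None,
    weights: LossWeights | None = None,
) -> float:
    """The declared weighted sum for one generator update."""
    variant = Variant(variant)
    w = weights or LossWeights()
    if variant is Variant.GAN:
        if reference_mae is None:
            raise ValueError("GAN total needs the paired MAE term")
        return w.gan_mae_to_adv * reference_mae + adv_gen
    if cycle is None:
        raise ValueError("cycle variants need the cycle term")
    out = w.cyc_cycle_to_adv * cycle + adv_gen
    if variant is Variant.RGGAN:
        if reference_mae is None:
            raise ValueError("RgGAN total needs the reference MAE term")
        out += w.rg_reference_weight * reference_mae
    return out


# ---------------------------------------------------------------------------
# training


def _as_batch(slices: list[np.ndarray]) -> np.ndarray:
    return np.stack(slices)[:, None].astype(np.float32)


def _l1_and_grad(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    d = a - b
    return float(np.mean(np.abs(d))), (np.sign(d) / d.size).astype(np.float32)


def _lsq_and_grad(scores: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    d = scores - target
    return float(np.mean(d * d)), (2.0 * d / d.size).astype(np.float32)


def train(
    bundle: ModelBundle,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig | None = None,
    weights: LossWeights | None = None,
) -> tuple[ModelBundle, list[LossRecord]]:
    """Alternating discriminator/generator updates over 2-D axial slice pairs.

    ``dataset`` holds paired normalized (mr, ct) slices; the cycle variants
    consume the two pools through independent shuffles (unpaired contract),
    while the paired terms (plain GAN, RgGAN reference) use the pairing.
    Deterministic given ``config.seed``; raises :class:`TrainingDiverged`
    on a non-finite loss.
    """
    if not dataset:
        raise ValueError("empty dataset")
    config = config or TrainConfig()
    w = weights or LossWeights()
    rng = np.random.default_rng(config.seed)
    opt_g = nn.Adam(bundle.generator_params(), config.beta1, config.beta2)
    opt_d = nn.Adam(bundle.discriminator_params(), config.beta1, config.beta2)
    cyc = bundle.variant is not Variant.GAN
    history: list[LossRecord] = []
    it = 0
    n = len(dataset)
    bs = config.batch_size

    def crop_pair(idx: list[int], offsets_rng) -> tuple[np.ndarray, np.ndarray]:
        mrs, cts = [], []
        # one offset per batch keeps every slice in the batch aligned
        sub = np.random.default_rng(offsets_rng.integers(0, 2**31))
        for i in idx:
            mr, ct = dataset[i]
            both = np.stack([mr, ct])
            cropped = crop_or_pad_array(both, config.crop_rows_cols, "random", 0.0, sub)
            mrs.append(cropped[0])
            cts.append(cropped[1])
        return _as_batch(mrs), _as_batch(cts)

    for epoch in range(1, config.total_epochs + 1):
        lr = config.lr_at_epoch(epoch)
        perm_mr = rng.permutation(n)
        perm_ct = rng.permutation(n)  # drawn for every variant: shared RNG stream
        for start in range(0, n - bs + 1, bs):
            idx_mr = perm_mr[start : start + bs].tolist()
            idx_ct = perm_ct[start : start + bs].tolist()
            mr, ct_paired = crop_pair(idx_mr, rng)
            mr_unp, ct_unp = crop_pair(idx_ct, rng)
            ct = ct_unp if cyc else ct_paired

            # generator forwards are reused for both updates: the
            # discriminator step does not modify generator parameters, so
            # the tapes stay valid for the generator update below
            fake_ct, tape1 = bundle.g_mri.forward(mr)
            if cyc:
                fake_mr, tape3 = bundle.g_ct.forward(ct)

            # ---- discriminator update (one step, generators frozen) ----
            opt_d.zero_grad()
            real_s, tape = bundle.d_ct.forward(ct)
            l_real, g = _lsq_and_grad(real_s, 1.0)
            bundle.d_ct.backward(tape, g)
            fake_s, tape = bundle.d_ct.forward(fake_ct)
            l_fake, g = _lsq_and_grad(fake_s, 0.0)
            bundle.d_ct.backward(tape, g)
            adv_dis = l_real + l_fake
            if cyc:
                real_s, tape = bundle.d_mri.forward(mr)
                l_real, g = _lsq_and_grad(real_s, 1.0)
                bundle.d_mri.backward(tape, g)
                fake_s, tape = bundle.d_mri.forward(fake_mr)
                l_fake, g = _lsq_and_grad(fake_s, 0.0)
                bundle.d_mri.backward(tape, g)
                adv_dis += l_real + l_fake
            opt_d.step(lr)

            # ---- generator update (discriminators frozen) ----
            opt_g.zero_grad()
            if not cyc:
                s, tape_d = bundle.d_ct.forward(fake_ct)
                adv_gen, gs = _lsq_and_grad(s, 1.0)
                g_fake = bundle.d_ct.backward(tape_d, gs)
                for p in bundle.d_ct.params():
                    p.grad[...] = 0  # frozen; discard the grads this pass left
                ref_mae, gmae = _l1_and_grad(fake_ct, ct_paired)
                bundle.g_mri.backward(tape1, g_fake + w.gan_mae_to_adv * gmae)
                cyc_term = None
                rec = LossRecord(it, adv_dis, adv_gen, None, ref_mae,
                                 total_loss(bundle.variant, adv_gen, None, ref_mae, w))
            else:
                rec_mr, tape2 = bundle.g_ct.forward(fake_ct)
                rec_ct, tape4 = bundle.g_mri.forward(fake_mr)

                s_ct, tape_dct = bundle.d_ct.forward(fake_ct)
                adv_ct, gs_ct = _lsq_and_grad(s_ct, 1.0)
                s_mr, tape_dmr = bundle.d_mri.forward(fake_mr)
                adv_mr, gs_mr = _lsq_and_grad(s_mr, 1.0)
                adv_gen = adv_ct + adv_mr

                l_cyc_ct, g_cyc_ct = _l1_and_grad(rec_ct, ct)
                l_cyc_mr, g_cyc_mr = _l1_and_grad(rec_mr, mr)
                cyc_term = 0.5 * (l_cyc_ct + l_cyc_mr)

                ref_mae = None
                g_ref = 0.0
                if bundle.variant is Variant.RGGAN:
                    ref_mae, g_ref_arr = _l1_and_grad(fake_ct, ct_paired)
                    g_ref = w.rg_reference_weight * g_ref_arr

                half_w = 0.5 * w.cyc_cycle_to_adv
                g_fake_mr = bundle.g_mri.backward(tape4, (half_w * g_cyc_ct).astype(np.float32))
                g_fake_mr = g_fake_mr + bundle.d_mri.backward(tape_dmr, gs_mr)
                bundle.g_ct.backward(tape3, g_fake_mr.astype(np.float32))

                g_fake_ct = bundle.g_ct.backward(tape2, (half_w * g_cyc_mr).astype(np.float32))
                g_fake_ct = g_fake_ct + bundle.d_ct.backward(tape_dct, gs_ct) + g_ref
                bundle.g_mri.backward(tape1, g_fake_ct.astype(np.float32))

                for p in bundle.discriminator_params():
                    p.grad[...] = 0
                rec = LossRecord(it, adv_dis, adv_gen, cyc_term, ref_mae,
                                 total_loss(bundle.variant, adv_gen, cyc_term,
                                            ref_mae if ref_mae is not None else 0.0, w)
                                 if bundle.variant is Variant.RGGAN
                                 else total_loss(bundle.variant, adv_gen, cyc_term, None, w))
            opt_g.step(lr)

            if not rec.is_finite():
                raise TrainingDiverged(rec)
            history.append(rec)
            it += 1
    return bundle, history


# ---------------------------------------------------------------------------
# volume inference


def generate_sct(
    bundle_or_generator,
    mr: VolumeGrid,
    ct_geometry: VolumeGrid,
    crop_rows_cols: tuple[int, int] | None = None,
    normalization: NormalizationSpec | None = None,
    batch: int = 4,
) -> VolumeGrid:
    """Translate a normalized MR volume into a synthetic CT in HU.

    Per axial slice: central crop to the training size, generator pass,
    zero-pad back to the preprocessed in-plane size; slices are then
    reassembled, resampled to the reference CT spacing and denormalized.
    Accepts a :class:`ModelBundle` or any generator with ``forward``.
    """
    gen = bundle_or_generator.g_mri if isinstance(bundle_or_generator, ModelBundle) else bundle_or_generator
    if mr.modality is not Modality.NORMALIZED:
        raise ValueError("generate_sct expects a normalized MR volume")
    rows_cols = mr.shape[1:]
    slices_out = []
    vals = mr.values.astype(np.float32)
    for start in range(0, mr.shape[0], batch):
        x = vals[start : start + batch][:, None]
        if crop_rows_cols is not None:
            x = crop_or_pad_array(x, crop_rows_cols, "center", 0.0)
        y, _ = gen.forward(x)
        y = crop_or_pad_array(y, rows_cols, "center", 0.0)
        slices_out.append(y[:, 0])
    out = np.clip(np.concatenate(slices_out, axis=0), -1.0, 1.0).astype(np.float64)
    vol = VolumeGrid(out, mr.spacing, mr.origin, Modality.NORMALIZED)
    if tuple(vol.spacing) != tuple(ct_geometry.spacing):
        vol = resample_volume(vol, ct_geometry.spacing, "linear", cval=-1.0)
    if vol.shape != ct_geometry.shape:
        v = vol.values
        fixed = np.full(ct_geometry.shape, -1.0)
        sl = tuple(slice(0, min(a, b)) for a, b in zip(ct_geometry.shape, v.shape))
        fixed[sl] = v[sl]
        vol = VolumeGrid(fixed, ct_geometry.spacing, ct_geometry.origin, Modality.NORMALIZED)
    sct = denormalize_ct(vol, normalization)
    return VolumeGrid(sct.values, ct_geometry.spacing, ct_geometry.origin, Modality.CT_HU)
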