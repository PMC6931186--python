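"""End-to-end segmentation pipeline: nine paths plus a fusion stage.

``MultiPathPipeline.fit`` trains one dual-encoder U-Net per (plane,
normalization) view on 2D slices, freezes them, then trains the 3D
convolutional post-processor on their stacked binarized outputs.
``predict`` runs all nine paths on a new case and fuses them with the
configured strategy (union, majority vote, or the learned 3D CNN).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fusion import Fusion3DNet, FuserConfig, assemble_stack, fuse
from .phantom import PhantomCase
from .training import TrainConfig, train_fuser, train_path
from .unet import DualUNet, PathNetConfig, path_forward
from .views import ALL_PATHS, NormScheme, PathInput, PlaneId, extract_slices, normalize_stack
from .volume_io import BrainVolume, GridSpec, LesionMask, flip_lr


@dataclass
class Case:
    """One subject: primary scan, auxiliary modality, optional truth mask.

    The auxiliary volume is a second modality (FLAIR) when available,
    otherwise the left-right mirrored primary scan.
    """

    case_id: str
    primary: BrainVolume
    auxiliary: BrainVolume
    mask: LesionMask | None = None

    @classmethod
    def from_volumes(cls, case_id: str, primary: BrainVolume,
                     auxiliary: BrainVolume | None = None,
                     mask: LesionMask | None = None) -> "Case":
        if auxiliary is None:
            auxiliary = flip_lr(primary)
        return cls(case_id=case_id, primary=primary, auxiliary=auxiliary, mask=mask)

    @classmethod
    def from_phantom(cls, pc: PhantomCase) -> "Case":
        return cls(case_id=pc.case_id, primary=pc.volume_a,
                   auxiliary=pc.volume_b, mask=pc.mask)


def as_cases(cases) -> list[Case]:
    return [c if isinstance(c, Case) else Case.from_phantom(c) for c in cases]


def _in_plane_shape(grid_shape: tuple[int, int, int],
                    plane: PlaneId) -> tuple[int, int]:
    dims = [s for a, s in enumerate(grid_shape) if a != plane.axis]
    return (dims[0], dims[1])


def build_view(case: Case, plane: PlaneId, scheme: NormScheme) -> PathInput:
    """One of the nine normalized views for a single case."""
    p_stack = extract_slices(case.primary, plane)
    a_stack = extract_slices(case.auxiliary, plane)
    return PathInput(
        plane=plane, scheme=scheme,
        primary_stack=normalize_stack(p_stack, scheme),
        auxiliary_stack=normalize_stack(a_stack, scheme),
        slice_index_map=np.arange(p_stack.shape[0]),
    )


class MultiPathPipeline:
    """Trainable nine-path 2.5D segmentation system.

    Parameters
    ----------
    grid
        Canonical voxel grid all cases are assumed to live on.
    base_filters
        Channel width of every path network (32 at full scale).
    path_train, fuser_train
        SGD recipes for the path and fuser stages.
    strategy
        Default fusion strategy for :meth:`predict`.
    seed
        Master seed; per-path seeds are derived from it.
    """

    def __init__(self, grid: GridSpec, base_filters: int = 32,
                 path_train: TrainConfig | None = None,
                 fuser_train: TrainConfig | None = None,
                 strategy: str = "cnn3d", seed: int = 0) -> None:
        self.grid = grid
        self.base_filters = base_filters
        self.path_train = path_train or TrainConfig()
        self.fuser_train = fuser_train or TrainConfig()
        self.strategy = strategy
        self.seed = seed
        self.path_nets: dict[tuple[PlaneId, NormScheme], DualUNet] = {}
        self.fuser: Fusion3DNet | None = None
        self.loss_traces: dict[str, list[float]] = {}
        ss = np.random.SeedSequence(seed)
        self._path_seeds = [int(s) % (2 ** 31)
                            for s in ss.generate_state(len(ALL_PATHS) + 2)]

    # -- training ----------------------------------------------------------
    def fit(self, cases) -> "MultiPathPipeline":
        cases = as_cases(cases)
        self._check_grid(cases)
        self.fit_paths(cases)
        if self.strategy == "cnn3d":
            self.fit_fuser(cases)
        return self

    def fit_paths(self, cases: list[Case]) -> None:
        for k, (plane, scheme) in enumerate(ALL_PATHS):
            cfg = PathNetConfig(
                base_filters=self.base_filters,
                in_plane_shape=_in_plane_shape(self.grid.target_shape, plane),
            )
            net = DualUNet(cfg, seed=self._path_seeds[k])
            data = []
            for case in cases:
                view = build_view(case, plane, scheme)
                mask_stack = extract_slices(case.mask.data, plane)
                data.append((view, mask_stack))
            tc = replace(self.path_train, seed=self._path_seeds[k] + 1)
            trace = train_path(data, tc, net)
            self.path_nets[(plane, scheme)] = net
            self.loss_traces[f"{plane.value}_{scheme.value}"] = trace

    def fit_fuser(self, cases: list[Case]) -> None:
        stacks, masks = [], []
        for case in cases:
            preds = self.predict_soft_paths(case)
            stacks.append(assemble_stack(preds, case.primary))
            masks.append(case.mask.data)
        self.fuser = Fusion3DNet(FuserConfig(strategy="cnn3d"),
                                 seed=self._path_seeds[-1])
        tc = replace(self.fuser_train, seed=self._path_seeds[-2])
        self.loss_traces["fuser"] = train_fuser(stacks, masks, tc, self.fuser)

    # -- inference ---------------------------------------------------------
    def predict_soft_paths(self, case: Case | PhantomCase) -> list[np.ndarray]:
        """The nine soft path volumes, in canonical path order."""
        if not self.path_nets:
            raise RuntimeError("pipeline is not fitted")
        case = as_cases([case])[0]
        preds = []
        for plane, scheme in ALL_PATHS:
            view = build_view(case, plane, scheme)
            preds.append(path_forward(view, self.path_nets[(plane, scheme)]))
        return preds

    def predict(self, case, strategy: str | None = None) -> np.ndarray:
        """Binary lesion mask for one case under the given fusion strategy."""
        case = as_cases([case])[0]
        preds = self.predict_soft_paths(case)
        return fuse(preds, case.primary, strategy or self.strategy, net=self.fuser)

    # -- persistence -------------------------------------------------------
    def save(self, model_dir) -> None:
        """Write one checkpoint per path plus the fuser and a config echo."""
        import json
        from pathlib import Path

        from .fusion import save_fuser
        from .unet import save_checkpoint

        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        for (plane, scheme), net in self.path_nets.items():
            save_checkpoint(net, model_dir / f"path_{plane.value}_{scheme.value}.npz",
                            extra={"plane": plane.value, "scheme": scheme.value})
        if self.fuser is not None:
            save_fuser(self.fuser, model_dir / "fuser.npz")
        meta = {
            "grid": list(self.grid.target_shape),
            "base_filters": self.base_filters,
            "strategy": self.strategy,
            "seed": self.seed,
            "loss_traces": self.loss_traces,
        }
        (model_dir / "pipeline.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, model_dir) -> "MultiPathPipeline":
        import json
        from pathlib import Path

        from .fusion import load_fuser
        from .unet import load_checkpoint

        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "pipeline.json").read_text())
        pipe = cls(GridSpec(target_shape=tuple(meta["grid"])),
                   base_filters=meta["base_filters"],
                   strategy=meta["strategy"], seed=meta["seed"])
        pipe.loss_traces = meta.get("loss_traces", {})
        for plane, scheme in ALL_PATHS:
            ckpt = model_dir / f"path_{plane.value}_{scheme.value}.npz"
            pipe.path_nets[(plane, scheme)] = load_checkpoint(ckpt)
        fuser_path = model_dir / "fuser.npz"
        if fuser_path.exists():
            pipe.fuser = load_fuser(fuser_path)
        return pipe

    # -- helpers -----------------------------------------------------------
    def _check_grid(self, cases: list[Case]) -> None:
        for case in cases:
            if case.primary.shape != self.grid.target_shape:
                raise ValueError(
                    f"case {case.case_id} shape {case.primary.shape} != grid "
                    f"{self.grid.target_shape}; conform volumes first")
            if case.mask is None:
                raise ValueError(f"case {case.case_id} has no training mask")


def desk_scale_pipeline(seed: int = 0, strategy: str = "cnn3d",
                        path_epochs: int = 6, fuser_epochs: int = 8
                        ) -> MultiPathPipeline:
    """Pipeline sized for CPU phantom runs on the reduced 48x64x48 grid.

    Narrow path networks (8 filters), batches of 8 slices, ~60 minibatches
    per epoch; the full-scale recipe (32 filters, batch 32, 50 epochs) stays
    available through the regular constructor.
    """
    grid = GridSpec(target_shape=(48, 64, 48))
    path_train = TrainConfig(batch_size=8, epochs=path_epochs,
                             steps_per_epoch=60, seed=seed)
    fuser_train = TrainConfig(batch_size=8, epochs=fuser_epochs,
                              steps_per_epoch=40, lr0=0.01, seed=seed)
    return MultiPathPipeline(grid, base_filters=8, path_train=path_train,
                             fuser_train=fuser_train, strategy=strategy,
                             seed=seed)
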