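"""Cluster weekday and weekend average profiles with TADPole.

Builds per-participant average series per segment, runs silhouette-driven
grid selection of (k, cutoff) independently for weekdays and weekends, and
writes assignments and the full grid scores under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from actipat import series as ser
from actipat.pipeline import ingest_stage
from actipat.tsclust import select_model

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    days, _, _ = ingest_stage(ROOT / "cohort")
    avg = ser.build_average_series(days)
    ser.average_series_frame(avg).to_csv(ROOT / "average_series.csv", index=False)
    for segment in ser.SEGMENTS:
        X = np.vstack([s.values for s in avg[segment]])
        model = select_model(X, k_grid=[2, 3, 4, 5, 6], window=14)
        sizes = np.bincount(model.assignment)
        print(
            f"{segment}: selected k={model.k}, cutoff={model.cutoff:.1f}, "
            f"silhouette={model.silhouette:.3f}, cluster sizes {sizes.tolist()}"
        )
        pd.DataFrame(
            {
                "participant_id": [s.participant_id for s in avg[segment]],
                "segment": segment,
                "cluster_id": model.assignment,
                "is_medoid": [i in model.medoids for i in range(len(avg[segment]))],
                "is_center": [i in model.centers for i in range(len(avg[segment]))],
            }
        ).to_csv(ROOT / f"assignments_{segment}.csv", index=False)
        model.grid.to_csv(ROOT / f"grid_scores_{segment}.csv", index=False)
    print(f"wrote assignments and grid scores under {ROOT}")


if __name__ == "__main__":
    main()
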