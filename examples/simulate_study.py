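"""Generate a small synthetic study and inspect its design and ground truth.

The generator emulates the experiment's structure: each subject completes
four sessions (cTBS/iTBS stimulation crossed with SEQ/RND practice) in a
counterbalanced visit order, each session holding a pre-task resting run,
a 16-block task run, and a post-task resting run, with hidden pattern
persistence between the runs.
"""

from mvcs import GeneratorConfig, generate_experiment

config = GeneratorConfig(
    n_subjects=4,
    rois={"dlpfc": 40, "hippocampus": 30},
    rest_volumes=120,
    seed=1,
)
study = generate_experiment(config)

print("Design (one row per session):")
print(study.design.to_string(index=False))

cd = study.data[("sub-01", "cSEQ")]
pre = cd.pre.roi_ts["dlpfc"]
task = cd.task.roi_ts["dlpfc"]
print(f"\npre-rest run: {pre.n_volumes} volumes at TR {pre.tr} s, "
      f"{pre.n_voxels} voxels")
print(f"task run:     {task.n_volumes} volumes at TR {task.tr} s, "
      f"{len([s for s in task.block_annotations if s.label == 'practice'])} "
      "practice blocks")

gt = study.ground_truth.table
print("\nHidden persistence (mean rho per pairing):")
print(gt.groupby("pairing")["rho"].mean().to_string())
print("\nThese rho values are what the similarity analysis should recover:")
print("higher rho between two runs -> more similar correlation structure.")
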