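"""Central defaults for the whole pipeline.

Every quantity that controls a stochastic protocol (trial counts, data
splits, training schedules, histogram resolution) lives here so that the
CLI, the library and the tests agree on a single set of conventions.
"""

# --- committor analysis ---------------------------------------------------
#: trajectories launched per shooting point
N_COMMITTOR_TRIALS = 100
#: a configuration is a transition state when 0.45 < p_A < 0.55
TS_WINDOW = (0.45, 0.55)
#: histogram bin width for p(p_A); 20 bins resolve the binomial reference
#: at 100 trials without empty-bin noise
HIST_BIN_WIDTH = 0.05

# --- committor-distribution subset selections -----------------------------
LAMBDA_SUBSET_HALFWIDTH = 0.05   # lambda = level +/- 0.05
RI_SUBSET_HALFWIDTH = 0.02       # r_I = level +/- 0.02 nm

# --- knowledge-based reaction coordinate lambda ---------------------------
#: reference values marking the free-energy minima (nm)
S6_REF = 1.18
RI_REF = 0.18

# --- network training ------------------------------------------------------
TRAIN_FRACTION = 0.72
VALIDATION_FRACTION = 0.08
TEST_FRACTION = 0.20
BATCH_SIZE = 128
SEARCH_EPOCHS = 50
REFINE_EPOCHS = 200
EARLY_STOP_PATIENCE = 10
LR_PLATEAU_PATIENCE = 7
LR_REDUCTION_FACTOR = 5.0
LR_FLOOR = 1e-5
#: probability clipping inside the likelihood loss
PROB_EPS = 1e-7

# --- hyperparameter search -------------------------------------------------
BEST_SUBSET_SIZE = 5
DEFAULT_SEARCH_TRIALS = 30

# --- free energy -----------------------------------------------------------
N_BLOCKS = 8
WHAM_TOL = 1e-7
WHAM_MAX_ITER = 100_000

# --- toy dynamics ----------------------------------------------------------
TOY_BARRIER_HEIGHT = 8.0     # k_BT
TOY_N_BATH = 8
TOY_N_NOISE = 8
TOY_FRICTION = 1.0
TOY_TIMESTEP = 0.01
TOY_COUPLING_RANGE = (0.1, 5.0)   # log-spaced per-bath couplings
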