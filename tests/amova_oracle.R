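# Independent one-way AMOVA oracle.
#
# The among/within sum-of-squares decomposition is taken from
# vegan::adonis2 (whose single-factor partition of squared dissimilarities
# is identical to the one-level AMOVA decomposition); variance components
# and Phi_ST are then derived from those SS by the method-of-moments
# formulas.  Usage: Rscript amova_oracle.R <dir> <n_instances>
# Reads <dir>/dist%02d.tsv and <dir>/groups%02d.txt, writes <dir>/oracle.tsv
# with columns: ss_among ss_within sigma2_among sigma2_within phi_st.

suppressMessages(library(vegan))
args <- commandArgs(TRUE)
dir <- args[1]
n_inst <- as.integer(args[2])
out <- file(file.path(dir, "oracle.tsv"), "w")
for (i in seq_len(n_inst)) {
  d <- as.matrix(read.table(file.path(dir, sprintf("dist%02d.tsv", i))))
  g <- factor(readLines(file.path(dir, sprintf("groups%02d.txt", i))))
  fit <- adonis2(as.dist(d) ~ g, permutations = 2)
  ss_among <- fit$SumOfSqs[1]
  ss_within <- fit$SumOfSqs[2]
  n <- length(g)
  sizes <- table(g)
  k <- length(sizes)
  ms_a <- ss_among / (k - 1)
  ms_w <- ss_within / (n - k)
  nbar <- (n - sum(sizes^2) / n) / (k - 1)
  s2w <- ms_w
  s2a <- (ms_a - ms_w) / nbar
  cat(sprintf(
    "%.17g\t%.17g\t%.17g\t%.17g\t%.17g\n",
    ss_among, ss_within, s2a, s2w, s2a / (s2a + s2w)
  ), file = out)
}
close(out)
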