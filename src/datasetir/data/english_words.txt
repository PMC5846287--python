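# Compact English recognition wordlist (one lowercase word per line).
# Authored for this package: common English vocabulary plus ordinary
# biomedical English. Deliberately small; point the lexicon builder at a
# full spell-check list for production use.
a
abdomen
ability
able
about
above
absence
abstract
abundance
access
accession
according
account
accurate
acid
across
action
active
activity
acute
adaptive
added
addition
additional
adipose
adult
affect
after
against
age
agent
aging
algorithm
all
allele
allow
almost
alone
along
also
alteration
although
among
amount
analysis
analyze
anatomy
and
animal
annotation
antibody
antigen
any
apoptosis
application
applied
approach
archive
area
array
article
assay
assembly
assess
assessment
associated
association
atlas
available
average
bacteria
bacterial
balance
based
baseline
basic
basis
be
because
become
been
before
behavior
being
below
benefit
best
between
binding
biological
biology
biomarker
biopsy
birth
blood
body
bone
both
brain
breast
but
by
calcium
can
cancer
candidate
capacity
carcinoma
cardiac
care
carried
case
catalog
cause
cell
cellular
center
central
certain
challenge
change
changes
characteristic
characterization
chemical
chemistry
childhood
children
chromatin
chromosome
chronic
class
classification
clinical
clone
cluster
code
cognitive
cohort
collected
collection
colon
combination
combined
common
community
comparative
compared
comparison
complete
complex
component
composition
compound
comprehensive
computational
concentration
concerning
condition
conducted
confirm
consistent
contain
content
context
contrast
control
copy
core
correlation
cortex
could
count
course
criteria
critical
cross
culture
current
cycle
daily
damage
data
database
dataset
day
death
decrease
deep
default
defect
deficiency
defined
degree
deletion
delivery
dementia
demographic
density
dependent
depression
depth
derived
description
design
detail
detailed
detection
determine
development
developmental
diabetes
diabetic
diagnosis
diagnostic
diet
dietary
difference
different
differential
differentiation
digital
dimension
direct
discovery
disease
disorder
distinct
distribution
diverse
diversity
division
document
domain
dominant
dose
double
down
drug
during
dynamic
dynamics
each
early
effect
effective
efficacy
efficiency
eight
either
electronic
element
embryo
embryonic
emission
enable
end
endothelial
energy
enrichment
environment
environmental
enzyme
epidemiology
epigenetic
epithelial
essential
established
estimate
evaluate
evaluation
event
evidence
evolution
exact
examination
examine
example
exclusion
exercise
exome
expanded
experiment
experimental
exposure
expression
extended
external
extract
factor
family
fat
feature
features
feedback
female
fetal
fiber
field
figure
file
final
finding
first
fish
five
fluid
focus
follow
following
food
for
form
format
formation
found
four
fraction
fragment
frequency
from
full
function
functional
fundamental
further
future
gain
gene
general
generated
generation
genetic
genome
genomic
genotype
given
gland
global
glucose
goal
gradient
grant
group
growth
has
have
health
healthy
heart
heat
height
hepatic
here
high
higher
highly
histology
history
homeostasis
hormone
hospital
host
hour
how
human
hybrid
identification
identified
identify
image
imaging
immune
immunity
impact
important
improve
in
incidence
include
included
inclusion
increase
increased
independent
index
indicate
individual
induced
infant
infection
inflammation
inflammatory
influence
information
inhibitor
initial
injection
injury
insulin
integrated
intensity
interaction
internal
intervention
into
intrinsic
investigate
investigation
involved
is
isolated
isolation
its
joint
key
kidney
kinase
knockout
knowledge
label
laboratory
large
late
layer
lead
learning
left
length
lesion
less
level
library
life
ligand
light
like
limit
limited
line
lineage
linked
lipid
liquid
list
literature
liver
local
location
long
longitudinal
loss
low
lower
lung
machine
magnetic
main
maintenance
major
male
malignant
mammalian
management
many
map
mapping
marker
mass
maternal
matrix
mature
may
mean
measure
measured
measurement
mechanism
media
medical
medicine
melanoma
member
membrane
memory
metabolic
metabolism
metadata
method
methylation
mice
microbial
microbiome
microscopy
middle
migration
mild
model
moderate
modification
molecular
molecule
monitoring
month
more
morphology
mortality
most
mother
motif
motor
mouse
movement
multiple
muscle
mutant
mutation
name
national
native
natural
nature
negative
nerve
network
neural
neuron
neuronal
new
nine
no
node
noise
normal
not
note
novel
nuclear
nucleotide
nucleus
number
nutrition
obesity
observation
observed
obtained
occurrence
of
offspring
often
old
on
once
one
only
onset
open
optical
optimal
or
oral
order
organ
organism
original
other
our
outcome
output
ovarian
over
overall
oxidative
oxygen
pain
pair
panel
paper
parameter
parent
part
partial
participant
particular
pathway
patient
pattern
pediatric
peptide
per
percent
performance
period
peripheral
phase
phenotype
physical
physiological
pilot
placebo
plant
plasma
platform
point
policy
pool
population
position
positive
possible
post
potential
power
practice
precision
predict
prediction
pregnancy
present
pressure
prevalence
prevention
previous
primary
prior
probe
procedure
process
processing
produce
product
profile
profiling
prognosis
progression
project
promoter
property
protein
protocol
provide
public
published
pulmonary
purpose
quality
quantitative
question
random
randomized
range
rare
rat
rate
ratio
raw
reaction
receptor
recombinant
record
recovery
recruitment
reduced
reduction
reference
region
regional
regression
regulation
regulatory
related
relationship
relative
release
relevant
renal
repair
repeat
replicate
report
repository
representative
required
research
resistance
resolution
resource
response
result
retinal
reveal
review
right
risk
role
safety
same
sample
sampling
scale
scan
score
screen
screening
search
second
secondary
section
seed
selection
sensitive
sensitivity
sequence
sequencing
series
serum
set
seven
severe
severity
sex
shape
shared
short
show
shown
signal
signaling
significant
similar
simple
single
site
six
size
skin
sleep
small
smoking
social
software
soil
source
spatial
species
specific
specificity
spectrometry
spectrum
speed
spinal
stability
stable
stage
standard
state
statistical
status
stem
step
stimulation
storage
strain
strategy
stress
stroke
strong
structural
structure
studies
study
subject
subset
subunit
such
summary
supplementary
support
surface
surgery
survey
survival
susceptibility
symptom
syndrome
synthesis
system
systematic
systemic
table
target
targeted
task
technique
technology
temperature
temporal
ten
term
tertiary
test
testing
that
the
therapeutic
therapy
there
thermal
these
this
three
threshold
through
throughput
time
tissue
to
tool
total
toxicity
tract
training
transcript
transcription
transcriptome
transfer
transgenic
transition
translation
transplant
treated
treatment
trial
tumor
two
type
under
understanding
unique
unit
unknown
untreated
up
update
uptake
use
used
using
validation
value
variable
variant
variation
vascular
vector
vehicle
version
vessel
view
viral
virus
visual
vitamin
vitro
vivo
volume
was
water
wave
we
week
weight
well
were
western
wheat
when
where
which
whole
wide
wild
will
with
within
without
women
work
year
yeast
yield
young
zebrafish
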