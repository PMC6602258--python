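# Common English words used to filter term dictionaries before scanning.
# One word per line, lower case.  Lines starting with '#' are ignored.
# The list mixes high-frequency function words with everyday nouns and
# verbs that collide with gene symbols or GO term names (e.g. "learning",
# "memory", "growth") and would otherwise match huge numbers of abstracts.
a
about
above
after
again
against
aging
all
also
an
and
any
are
arm
as
at
axis
back
bad
balance
base
be
because
been
before
behavior
behaviour
being
below
between
big
binding
bite
blood
body
bone
both
bridge
bud
but
by
call
can
cap
car
care
carrier
case
cell
center
chain
change
channel
clock
close
cold
common
complex
control
could
cycle
damage
dance
dark
death
deep
defense
development
digestion
division
do
does
done
down
drink
drive
drug
dry
during
each
early
eat
egg
end
energy
envelope
even
face
factor
fall
family
far
fast
fat
fate
feeding
few
fiber
field
fight
fine
fire
first
flight
flow
food
for
form
formation
free
from
fusion
gap
gate
general
give
good
great
growth
had
hand
hard
has
have
he
head
hearing
heart
heat
help
her
here
high
him
his
hold
host
hot
house
how
if
in
into
is
it
its
join
jump
just
keep
key
kill
kind
know
large
last
late
lead
learning
left
less
life
light
like
line
link
little
local
long
look
low
made
maintenance
make
man
many
map
mass
may
meal
mean
memory
men
might
mind
more
most
motion
mouth
move
movement
much
must
near
nest
net
new
next
no
noise
none
nor
not
now
nurse
of
off
old
on
once
one
only
open
or
order
other
our
out
over
own
pain
pair
part
past
pattern
peace
people
piece
place
plan
plant
play
point
pore
power
present
process
pump
put
rain
range
rate
reading
red
release
repair
response
rest
right
ring
rise
road
rock
run
said
salt
same
say
sea
secretion
see
seed
sense
set
sharp
she
shell
shock
short
should
side
sight
signal
signaling
sleep
slow
small
smell
so
some
song
sound
speech
spindle
spring
start
state
stem
still
stop
storage
stress
strong
such
sun
swim
system
tail
take
target
taste
than
that
the
their
them
then
there
these
they
this
those
through
time
to
tone
tooth
touch
toxin
track
transport
trap
tree
turn
two
under
up
upon
use
very
vision
voice
walk
wall
warm
was
water
wave
way
we
well
were
what
when
where
which
while
white
who
why
wide
will
wing
with
word
work
would
wound
year
yes
yet
you
young
your
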