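word,aoa,concreteness,valence,arousal,frequency
abstraction,4.96,4.16,7.42,6.52,4.19
again,6.77,1.27,6.01,6.97,1.86
alone,10.45,1.73,2.03,2.18,1.22
animal,5.02,4.24,2.09,2.23,2.98
apple,3.73,1.76,6.37,6.46,1.12
artifact,6.23,2.84,6.1,4.02,0.52
assist,10.73,1.86,7.38,4.43,2.1
automobile,9.03,3.47,4.08,2.21,1.38
bad,8.79,4.25,6.08,3.05,1.17
bank,3.27,3.53,6.03,4.26,2.65
big,3.82,3.9,5.21,5.74,0.61
bird,10.76,2.04,6.15,4.69,2.5
boat,6.32,1.75,2.01,4.93,4.42
bread,5.05,3.97,4.65,2.7,3.62
car,3.47,3.68,3.65,6.61,3.17
care,10.44,3.84,5.0,6.85,0.88
cat,10.7,3.81,4.26,4.45,2.21
chat,5.1,1.83,3.6,2.04,3.64
child,9.42,4.7,2.27,2.51,4.44
communicate,2.77,2.39,3.56,4.5,2.89
companion,7.71,4.84,2.29,2.76,3.78
create,5.76,3.07,2.61,2.91,3.54
creature,10.27,4.99,3.03,3.13,3.1
day,9.24,3.62,6.91,5.26,0.89
doctor,8.8,3.28,7.22,2.47,3.25
dog,8.74,2.97,4.26,4.89,2.34
door,4.65,1.6,4.88,3.15,0.41
eat,6.31,4.86,7.15,4.97,2.43
elderly,9.73,4.58,5.89,6.13,1.07
emotion,10.95,4.43,2.43,2.03,1.36
entity,10.44,2.96,4.51,3.62,3.24
fast,11.48,4.71,3.9,4.54,2.17
feel,7.25,4.71,4.44,4.79,1.04
feeling,8.5,3.24,3.42,5.38,0.49
fish,5.06,2.73,2.96,3.6,4.27
food,5.64,2.32,6.85,6.92,3.11
frequently,11.56,1.51,4.08,4.58,3.87
friend,10.3,4.2,6.29,3.11,1.66
fruit,9.32,1.81,2.5,2.97,4.47
garden,9.0,3.72,5.21,4.4,2.54
give,3.15,3.16,6.67,5.57,1.29
glad,8.04,4.47,4.58,2.49,0.42
go,3.82,3.37,6.0,4.26,1.61
good,6.15,4.33,7.37,2.25,1.91
happiness,7.09,4.01,2.6,3.3,3.22
happy,8.52,2.92,6.11,5.45,4.5
health,6.35,4.62,5.03,4.07,2.5
help,6.17,3.9,4.08,3.61,2.28
home,3.19,4.36,6.46,3.77,2.11
hound,5.02,4.26,2.01,6.5,1.49
house,7.51,2.03,6.31,4.2,4.2
husband,3.2,4.74,6.27,2.9,1.76
ill,4.48,4.48,5.4,4.02,2.33
individual,9.79,1.24,2.07,2.17,1.06
joy,8.62,1.99,5.48,2.47,2.05
kid,3.09,2.47,4.56,3.29,4.26
kitty,5.46,3.48,3.81,4.27,3.75
large,9.3,2.33,7.81,3.85,4.0
little,11.85,3.65,2.76,3.83,0.32
location,3.73,2.55,4.22,2.41,0.95
lonely,7.83,4.22,3.17,2.93,2.36
love,6.97,4.79,7.97,5.18,4.13
make,10.14,1.22,2.48,2.54,1.41
man,7.28,4.7,7.38,3.27,3.32
money,8.78,2.04,7.82,3.35,2.57
move,10.23,1.37,4.77,6.45,3.65
narrate,11.81,1.44,3.42,5.58,2.59
narrative,10.36,3.07,3.05,4.17,3.13
neighbor,11.98,1.7,2.64,6.0,2.89
night,5.06,4.08,2.15,5.36,0.8
object,5.51,2.77,4.56,3.02,2.6
often,11.36,1.89,2.35,3.9,3.23
old,6.35,1.42,6.6,5.6,3.09
organism,7.04,4.5,5.26,5.93,3.27
perceive,10.37,2.77,5.9,6.98,0.79
person,2.74,4.17,4.84,3.33,1.67
physician,10.56,3.24,3.37,2.13,1.34
plant,2.57,2.15,4.28,2.49,2.06
play,4.94,3.59,4.96,6.45,1.88
quickly,6.08,1.54,5.92,5.58,1.18
quiet,10.35,3.07,4.7,5.12,2.75
quietly,4.06,4.87,7.34,6.02,4.17
river,9.74,4.15,5.86,5.22,2.38
run,11.31,4.57,2.7,3.16,3.98
sad,9.91,4.31,2.22,4.49,1.92
sadness,7.84,2.34,2.29,2.88,0.62
see,11.91,3.74,7.54,6.61,2.06
sick,7.92,4.55,3.64,6.68,3.05
sit,9.4,2.09,2.98,5.14,1.63
slowly,7.11,1.81,4.75,5.17,1.75
small,6.98,4.14,6.58,4.23,2.69
sorrow,3.07,3.45,3.88,3.31,1.53
speak,6.92,2.27,4.35,6.25,4.1
spouse,3.02,3.76,7.23,5.86,2.84
story,8.22,4.11,2.66,3.08,2.57
stream,3.22,4.17,7.03,7.0,4.38
tale,3.31,1.59,2.46,3.23,1.34
talk,4.75,4.84,6.22,3.46,1.77
tell,10.75,1.32,4.88,6.13,1.79
tend,3.32,2.29,4.66,2.33,1.15
time,6.95,3.16,6.5,3.9,1.18
town,9.87,3.03,6.7,3.76,0.92
travel,9.36,2.43,6.93,5.21,0.59
tree,8.09,4.51,7.39,2.19,3.03
unhappy,6.21,4.88,3.82,5.83,0.5
village,8.18,1.83,5.94,2.15,3.07
visit,6.83,1.3,7.34,3.05,3.52
walk,3.89,3.61,2.77,5.33,3.83
watch,7.08,2.77,6.6,2.26,3.29
water,4.77,3.99,2.85,4.35,3.58
wife,4.47,3.7,2.92,2.92,2.35
window,11.56,2.47,3.24,6.45,3.85
woman,5.39,3.57,2.24,3.24,0.57
word,10.03,4.63,4.84,5.44,0.9
work,6.64,3.38,2.57,3.05,1.41
yard,6.68,4.47,5.32,6.27,4.08
year,3.65,3.27,6.25,3.59,4.37
young,10.77,1.7,2.35,5.03,4.05
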